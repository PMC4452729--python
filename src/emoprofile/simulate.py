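"""Synthetic behavioral cohort generator.

Generates 2 (prenatal: SAL/VPA) x 3 (environment: ST/UE/PE) cohorts whose
statistical structure matches what the downstream analysis assumes: five
inter-correlated emotionality measures drawn per design cell from a
multivariate normal with compound-symmetry correlation, rare binary
perseveration events enriched in the VPA group, heterogeneous variance in
the VPA-PE cell, and biochemical variables (protein immunoreactivity,
corticosterone) coupled to each animal's latent emotionality deviation
with opposite signs in the SAL and VPA groups.

Randomness is one shared stream per cohort, split per animal by counter
(``default_rng([seed, animal_index])``), so adding a measure never
perturbs draws for earlier animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, candidate_measures

logger = logging.getLogger(__name__)

CELLS = (
    ("SAL", "ST"), ("SAL", "UE"), ("SAL", "PE"),
    ("VPA", "ST"), ("VPA", "UE"), ("VPA", "PE"),
)

#: Emotionality measures simulated per cell (order fixed).
EMOTIONALITY_MEASURES = tuple(m.name for m in candidate_measures(DEFAULT_CATALOG))
_INVERTED = {m.name: m.inverted for m in DEFAULT_CATALOG}

PROTEIN_COLUMNS = ("S1_GluN2B", "dHip_CaMKII", "vHip_GluN1", "Amy_GluN2B")
CORT_COLUMN = "cort_plasma"

# Latent emotionality level programmed per cell (unitless, ~z scale):
# VPA-ST highest, VPA-PE lowest, enriched SAL above SAL-ST.
_EMO_LEVEL = {
    ("SAL", "ST"): -0.50, ("SAL", "UE"): 0.10, ("SAL", "PE"): 0.10,
    ("VPA", "ST"): 0.80, ("VPA", "UE"): 0.60, ("VPA", "PE"): -0.60,
}

# Raw-scale anchors per measure: baseline, sd, and the raw-units shift per
# unit of programmed emotionality (negative for inverted scales). Baselines
# sit >= 2.5 sd from the nearest range bound so clamping is rare.
_MEASURE_BASE = {
    "open_arm_time": (28.0, 6.0, -10.0),       # s, inverted scale
    "training_freezing": (35.0, 10.0, 12.0),   # %
    "context_freezing_lt": (45.0, 12.0, 15.0),  # %
    "pretone_freezing_lt": (30.0, 9.0, 10.0),  # %
    "tone_freezing_lt": (50.0, 12.0, 15.0),    # %
}
_MEASURE_BOUNDS = {
    "open_arm_time": (0.0, np.inf),
    "training_freezing": (0.0, 100.0),
    "context_freezing_lt": (0.0, 100.0),
    "pretone_freezing_lt": (0.0, 100.0),
    "tone_freezing_lt": (0.0, 100.0),
    "social_preference": (0.0, 1.0),
    "hotplate_latency": (0.0, np.inf),
    "epm_distance": (0.0, np.inf),
    "head_dips": (0.0, np.inf),
}

# Social preference cell means: VPA withdrawal in ST, reversal in PE,
# inflated variance in VPA-PE (F-ratio ~4 vs SAL-PE).
_SOCIAL_MEAN = {
    ("SAL", "ST"): 0.68, ("SAL", "UE"): 0.66, ("SAL", "PE"): 0.60,
    ("VPA", "ST"): 0.58, ("VPA", "UE"): 0.62, ("VPA", "PE"): 0.68,
}
_SOCIAL_SD = {cell: 0.08 for cell in CELLS}
_SOCIAL_SD[("SAL", "PE")] = 0.065
_SOCIAL_SD[("VPA", "PE")] = 0.13

_OPEN_ARM_SD_VPA_PE = 12.0  # F-ratio (12/6)^2 = 4 vs SAL-PE

# Coupling of biochemistry to the latent emotionality deviation, in IR
# percent (or ng/ml for CORT) per latent sd; opposite signs by group.
_DEFAULT_PROTEIN_EFFECT = {
    "S1_GluN2B": {"SAL": 8.0, "VPA": -12.0},
    "dHip_CaMKII": {"SAL": 8.0, "VPA": -12.0},
    "vHip_GluN1": {"SAL": -8.0, "VPA": 12.0},
    "Amy_GluN2B": {"SAL": 8.0, "VPA": -12.0},
}
_DEFAULT_CORT_EFFECT = {"SAL": -6.0, "VPA": 10.0}

# Multiplicative assay-batch gains on raw band volumes; removed again by
# within-batch reference normalization.
_BATCH_GAIN = {1: 1.0, 2: 1.3, 3: 0.8}


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    ``cell_means``/``cell_sds`` are keyed ``(prenatal, environment)`` ->
    ``{measure: value}`` on the raw measure scale. ``inter_measure_r`` is
    the compound-symmetry correlation among the emotionality measures on
    their *oriented* (emotionality) scale. Perseveration rates are per
    prenatal group. Protein/CORT effects are signed couplings to the
    latent emotionality deviation, keyed variable -> prenatal group.
    """

    n_per_cell: Mapping[tuple[str, str], int]
    cell_means: Mapping[tuple[str, str], Mapping[str, float]]
    cell_sds: Mapping[tuple[str, str], Mapping[str, float]]
    inter_measure_r: float = 0.335
    perseveration_rate: Mapping[str, float] = field(
        default_factory=lambda: {"SAL": 2 / 54, "VPA": 10 / 53}
    )
    protein_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_PROTEIN_EFFECT
    )
    cort_effect: Mapping[str, float] = field(default_factory=lambda: _DEFAULT_CORT_EFFECT)
    social_mean: Mapping[tuple[str, str], float] = field(default_factory=lambda: _SOCIAL_MEAN)
    social_sd: Mapping[tuple[str, str], float] = field(default_factory=lambda: _SOCIAL_SD)
    seed: int = 0

    def validate(self) -> None:
        for cell in self.n_per_cell:
            if cell not in CELLS:
                raise ValueError(f"unknown design cell {cell!r}")
            if self.n_per_cell[cell] < 0:
                raise ValueError(f"negative n for cell {cell!r}")
        for cell, sds in self.cell_sds.items():
            for name, sd in sds.items():
                if sd <= 0:
                    raise ValueError(f"non-positive sd for {name!r} in cell {cell!r}")
        if not (0 <= self.inter_measure_r < 1):
            raise ValueError("inter_measure_r must be in [0, 1)")
        for grp, rate in self.perseveration_rate.items():
            if not (0 <= rate <= 1):
                raise ValueError(f"perseveration rate for {grp!r} outside [0, 1]")
        k = len(EMOTIONALITY_MEASURES)
        if np.linalg.eigvalsh(_cs_matrix(k, self.inter_measure_r)).min() <= 0:
            raise ValueError("compound-symmetry correlation is not positive definite")


def _cs_matrix(k: int, r: float) -> np.ndarray:
    return np.full((k, k), r) + (1 - r) * np.eye(k)


def default_effects(seed: int = 0) -> CohortConfig:
    """Default study conditions: n = 18 per cell (17 in VPA-PE), programmed
    cell means ordering VPA-ST highest and VPA-PE lowest on emotionality,
    enriched SAL above SAL-ST, compound-symmetry r = 0.335, rare
    perseveration enriched in VPA, and a ~4x variance ratio for VPA-PE vs
    SAL-PE on EPM open-arm time and social preference."""
    n = {cell: 18 for cell in CELLS}
    n[("VPA", "PE")] = 17
    means: dict[tuple[str, str], dict[str, float]] = {}
    sds: dict[tuple[str, str], dict[str, float]] = {}
    for cell in CELLS:
        level = _EMO_LEVEL[cell]
        means[cell] = {}
        sds[cell] = {}
        for m, (base, sd, slope) in _MEASURE_BASE.items():
            means[cell][m] = base + slope * level
            sds[cell][m] = sd
    sds[("VPA", "PE")]["open_arm_time"] = _OPEN_ARM_SD_VPA_PE
    return CohortConfig(n_per_cell=n, cell_means=means, cell_sds=sds, seed=seed)


def _animal_rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng([seed, counter])


def generate(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a validated cohort DataFrame.

    Deterministic given ``config.seed`` (or the ``seed`` override). Range
    violations are clamped to the measure bounds; clamping more than 1% of
    draws is logged as a warning because it distorts the programmed
    means/correlations.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    k = len(EMOTIONALITY_MEASURES)
    chol = np.linalg.cholesky(_cs_matrix(k, config.inter_measure_r))

    rows: list[dict] = []
    counter = 0
    n_clamped = 0
    n_draws = 0
    for cell in CELLS:
        prenatal, env = cell
        n = config.n_per_cell.get(cell, 0)
        for i in range(n):
            rng = _animal_rng(config.seed, counter)
            # correlated emotionality deviations on the oriented scale
            z = chol @ rng.standard_normal(k)
            latent = z.mean()
            row: dict = {
                "animal_id": f"{prenatal}-{env}-{i + 1:02d}",
                "litter_id": f"{prenatal}-L{(counter % 12) + 1:02d}",
                "prenatal": prenatal,
                "environment": env,
                "batch": (counter % 3) + 1,
            }
            for j, m in enumerate(EMOTIONALITY_MEASURES):
                sign = -1.0 if _INVERTED[m] else 1.0
                raw = config.cell_means[cell][m] + sign * config.cell_sds[cell][m] * z[j]
                lo, hi = _MEASURE_BOUNDS[m]
                clipped = min(max(raw, lo), hi)
                n_clamped += clipped != raw
                n_draws += 1
                row[m] = clipped
            # held-out behaviors: sociability (anti-correlated with latent
            # emotionality in VPA), nociception, locomotion, head dips
            sp = (
                config.social_mean[cell]
                + config.social_sd[cell]
                * (rng.standard_normal() - (0.4 if prenatal == "VPA" else 0.1) * latent)
            )
            row["social_preference"] = min(max(sp, 0.0), 1.0)
            hp = 10.0 + 2.5 * rng.standard_normal() + (0.8 if prenatal == "VPA" else -0.2) * latent
            row["hotplate_latency"] = max(hp, 0.0)
            row["epm_distance"] = max(1400.0 + 250.0 * rng.standard_normal() - 80.0 * latent, 0.0)
            row["head_dips"] = max(8.0 + 3.0 * rng.standard_normal() - 1.5 * latent, 0.0)
            row["perseveration"] = bool(
                rng.random() < config.perseveration_rate[prenatal]
            )
            gain = _BATCH_GAIN[row["batch"]]
            for prot, eff in config.protein_effect.items():
                ir_percent = 100.0 + eff[prenatal] * latent + 12.0 * rng.standard_normal()
                row[prot] = max(gain * 50.0 * ir_percent, 0.0)  # raw band volume
            row[CORT_COLUMN] = max(
                60.0 + config.cort_effect[prenatal] * latent + 12.0 * rng.standard_normal(),
                0.0,
            )
            rows.append(row)
            counter += 1

    if n_draws and n_clamped / n_draws >= 0.01:
        logger.warning(
            "range clamping altered %.2f%% of emotionality draws; programmed "
            "means/correlations may be distorted", 100 * n_clamped / n_draws,
        )
    df = pd.DataFrame(rows)
    df["perseveration"] = df["perseveration"].astype("boolean")
    return df


def empirical_inter_measure_r(cohort: pd.DataFrame) -> float:
    """Mean pairwise correlation of the oriented emotionality measures.

    Measures are oriented (inverted scales negated), then centered and
    scaled within each design cell before pooling, so the estimate
    recovers the configured compound-symmetry correlation rather than
    correlation induced by cell-mean differences.
    """
    cols = {}
    for m in EMOTIONALITY_MEASURES:
        v = cohort[m].astype(float)
        cols[m] = -v if _INVERTED[m] else v
    Z = pd.DataFrame(cols)
    cell = cohort["prenatal"].astype(str) + "-" + cohort["environment"].astype(str)
    Z = Z.groupby(cell, observed=True).transform(lambda c: (c - c.mean()) / c.std(ddof=1))
    R = Z.corr().to_numpy()
    k = R.shape[0]
    return float(R[~np.eye(k, dtype=bool)].mean())


def reference_mask(df: pd.DataFrame) -> np.ndarray:
    """Boolean mask of the IR normalization reference animals (SAL-ST)."""
    return ((df["prenatal"] == "SAL") & (df["environment"] == "ST")).to_numpy()
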
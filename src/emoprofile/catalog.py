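"""Catalog of behavioral measures.

The catalog is the single source of truth for which columns of a cohort
table are behavioral measures, what unit they carry, whether their scale
must be inverted before emotionality scoring (higher raw value = lower
emotionality), and whether they are candidates for the composite score or
held out for cluster "predicted" profiling only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

ROLE_CANDIDATE = "emotionality_candidate"
ROLE_PREDICTED = "predicted_only"
_ROLES = (ROLE_CANDIDATE, ROLE_PREDICTED)


@dataclass(frozen=True)
class MeasureDefinition:
    """One named behavioral measure.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    unit : str
        Physical unit ("s", "%", "cm", "index", "count").
    inverted : bool
        True if a higher raw value means *lower* emotionality, so the
        z-scored column must be negated before entering the composite.
    role : str
        ``"emotionality_candidate"`` (eligible for the internal-consistency
        subset search) or ``"predicted_only"`` (held out, used only to
        characterize clusters).
    """

    name: str
    unit: str
    inverted: bool = False
    role: str = ROLE_CANDIDATE

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r} for measure {self.name!r}")


#: Default measure catalog: five fear/anxiety readouts that are candidates
#: for the composite emotionality score (EPM open-arm time on an inverted
#: scale, fear acquisition, and three long-term fear-memory freezing
#: percentages), plus held-out sociability/nociception/locomotion readouts.
DEFAULT_CATALOG: tuple[MeasureDefinition, ...] = (
    MeasureDefinition("open_arm_time", "s", inverted=True, role=ROLE_CANDIDATE),
    MeasureDefinition("training_freezing", "%", role=ROLE_CANDIDATE),
    MeasureDefinition("context_freezing_lt", "%", role=ROLE_CANDIDATE),
    MeasureDefinition("pretone_freezing_lt", "%", role=ROLE_CANDIDATE),
    MeasureDefinition("tone_freezing_lt", "%", role=ROLE_CANDIDATE),
    MeasureDefinition("social_preference", "index", role=ROLE_PREDICTED),
    MeasureDefinition("hotplate_latency", "s", role=ROLE_PREDICTED),
    MeasureDefinition("epm_distance", "cm", role=ROLE_PREDICTED),
    MeasureDefinition("head_dips", "count", role=ROLE_PREDICTED),
)


def candidate_measures(catalog: Sequence[MeasureDefinition]) -> list[MeasureDefinition]:
    return [m for m in catalog if m.role == ROLE_CANDIDATE]


def predicted_measures(catalog: Sequence[MeasureDefinition]) -> list[MeasureDefinition]:
    return [m for m in catalog if m.role == ROLE_PREDICTED]


def measure_names(catalog: Sequence[MeasureDefinition]) -> list[str]:
    return [m.name for m in catalog]


def validate_catalog(catalog: Iterable[MeasureDefinition]) -> tuple[MeasureDefinition, ...]:
    cat = tuple(catalog)
    names = [m.name for m in cat]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate measure names in catalog: {sorted(dupes)}")
    return cat


def load_catalog(path: str | Path) -> tuple[MeasureDefinition, ...]:
    """Load a measure catalog from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"catalog file {path} must contain a YAML list")
    return validate_catalog(MeasureDefinition(**entry) for entry in raw)


def save_catalog(catalog: Sequence[MeasureDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(m) for m in catalog], fh, sort_keys=False)
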
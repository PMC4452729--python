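"""End-to-end orchestration of the analysis stages.

Each stage is a plain function taking/returning in-memory objects, so the
CLI stays a thin shell: simulate -> score -> stats -> cluster -> report.
All file outputs carry a ``#`` metadata header (tool version, seed,
config hash) and are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DEFAULT_CATALOG, MeasureDefinition, candidate_measures, predicted_measures
from .clustering import WardClusterer, complete_rows, percent_of_group, profile, to_newick
from .cohort import normalize_ir, write_cohort
from .scoring import EmotionalityScorer
from .simulate import CORT_COLUMN, PROTEIN_COLUMNS
from .stats import (
    barnard_exact,
    bonferroni_pairwise,
    fisher_exact,
    one_way_anova,
    spearman_rho,
    two_way_anova,
)

logger = logging.getLogger(__name__)


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def metadata(seed: int | None, cfg) -> dict:
    return {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
    }


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def write_json(obj, path: str | Path, meta: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump({"meta": dict(meta), **obj}, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def normalize_biochemistry(cohort: pd.DataFrame) -> pd.DataFrame:
    """Replace raw protein band volumes with within-batch normalized IR.

    Each protein column becomes percent of the mean IR of the SAL-ST
    animals run in the same assay batch. Requires ``batch``; a no-op for
    cohorts without protein columns.
    """
    prots = [c for c in PROTEIN_COLUMNS if c in cohort.columns]
    if not prots or "batch" not in cohort.columns:
        return cohort
    out = cohort.copy()
    ref = ((cohort["prenatal"] == "SAL") & (cohort["environment"] == "ST")).to_numpy()
    for c in prots:
        out[c] = normalize_ir(cohort[c].to_numpy(float), cohort["batch"].to_numpy(), ref)
    return out


def score_stage(
    cohort: pd.DataFrame,
    catalog: Sequence[MeasureDefinition] = DEFAULT_CATALOG,
    min_size: int = 3,
) -> tuple[pd.Series, EmotionalityScorer]:
    """Fit the emotionality scorer on the pooled cohort and score it."""
    scorer = EmotionalityScorer(catalog=catalog, min_size=min_size).fit(cohort)
    scores = scorer.score_frame(cohort)
    scores.index = cohort["animal_id"]
    return scores, scorer


def stats_stage(
    cohort: pd.DataFrame,
    scores: pd.Series,
    catalog: Sequence[MeasureDefinition] = DEFAULT_CATALOG,
    barnard_grid_step: float = 0.001,
) -> pd.DataFrame:
    """Tidy table of the group-level tests.

    Per measure (and the composite score): the 2x3 factorial ANOVA terms
    and the Bonferroni-corrected within-environment SAL-vs-VPA
    comparisons. For the binary perseveration flag: pooled Fisher exact
    test and per-environment Barnard exact tests.
    """
    df = cohort.copy()
    df["emotionality_score"] = scores.reindex(df["animal_id"]).to_numpy()
    rows = []
    measures = [m.name for m in catalog] + ["emotionality_score"]
    for name in measures:
        if name not in df.columns:
            continue
        try:
            tab = two_way_anova(df[name], df["prenatal"], df["environment"])
        except ValueError as err:
            logger.warning("ANOVA skipped for %s: %s", name, err)
            continue
        for term in ("factor_a", "factor_b", "interaction"):
            pretty = {"factor_a": "prenatal", "factor_b": "environment"}.get(term, term)
            rows.append(
                dict(test="anova2", measure=name, groups=pretty,
                     statistic=tab.loc[term, "F"],
                     df=f"({tab.loc[term, 'df']:.0f}, {tab.loc['residual', 'df']:.0f})",
                     p_raw=tab.loc[term, "p"], p_adjusted=np.nan)
            )
        for res in bonferroni_pairwise(df, name):
            rows.append(
                dict(test="welch_t" if res.welch_applied else "student_t",
                     measure=name, groups=f"{res.group_a} vs {res.group_b}",
                     statistic=res.statistic, df=f"{res.df:.1f}",
                     p_raw=res.p_raw, p_adjusted=res.p_adjusted)
            )
    if "perseveration" in df.columns:
        pers = df["perseveration"].astype("boolean")
        counts = {}
        for grp in ("VPA", "SAL"):
            mask = df["prenatal"] == grp
            counts[grp] = (int((pers[mask] == True).sum()), int(mask.sum()))  # noqa: E712
        table = [
            [counts["VPA"][0], counts["VPA"][1] - counts["VPA"][0]],
            [counts["SAL"][0], counts["SAL"][1] - counts["SAL"][0]],
        ]
        fres = fisher_exact(table)
        rows.append(dict(test="fisher_exact", measure="perseveration",
                         groups="VPA vs SAL (pooled)", statistic=np.nan, df="",
                         p_raw=fres.p_two_sided, p_adjusted=np.nan))
        for env in ("ST", "UE", "PE"):
            sub = df[df["environment"] == env]
            t = []
            for grp in ("VPA", "SAL"):
                mask = sub["prenatal"] == grp
                x = int((sub.loc[mask, "perseveration"].astype("boolean") == True).sum())  # noqa: E712
                t.append([x, int(mask.sum()) - x])
            bres = barnard_exact(t, grid_step=barnard_grid_step)
            rows.append(dict(test="barnard_exact", measure="perseveration",
                             groups=f"VPA vs SAL ({env})", statistic=bres.statistic,
                             df=f"pi_sup={bres.pi_sup:.3f}",
                             p_raw=bres.p_two_sided, p_adjusted=np.nan))
    # behavior-protein associations and environment effects, per prenatal group
    norm = normalize_biochemistry(df)
    prots = [c for c in (*PROTEIN_COLUMNS, CORT_COLUMN) if c in norm.columns]
    for grp in ("SAL", "VPA"):
        sub = norm[norm["prenatal"] == grp]
        for c in prots:
            try:
                rho, p = spearman_rho(sub["emotionality_score"], sub[c])
                rows.append(dict(test="spearman", measure=c,
                                 groups=f"{grp}: score vs {c}", statistic=rho,
                                 df=f"{sub[[c, 'emotionality_score']].dropna().shape[0]}",
                                 p_raw=p, p_adjusted=np.nan))
                tab = one_way_anova(sub[c], sub["environment"])
                rows.append(dict(test="anova1", measure=c,
                                 groups=f"{grp}: environment", statistic=tab.loc["factor", "F"],
                                 df=f"({tab.loc['factor', 'df']:.0f}, {tab.loc['residual', 'df']:.0f})",
                                 p_raw=tab.loc["factor", "p"], p_adjusted=np.nan))
            except ValueError as err:
                logger.warning("biochemical test skipped for %s/%s: %s", grp, c, err)
    return pd.DataFrame(rows)


def cluster_stage(
    cohort: pd.DataFrame,
    scores: pd.Series,
    scorer: EmotionalityScorer,
    k: int = 4,
) -> dict:
    """Per-prenatal-group Ward clustering and cluster profiles.

    Clustering runs separately for SAL and VPA on pooled-cohort z-scores
    of the selected items; profiles cover the core measures plus held-out
    behaviors, protein IR and corticosterone when present.
    """
    cohort = normalize_biochemistry(cohort)
    Zall = scorer.z_matrix(cohort)
    Zall.index = cohort["animal_id"]
    core = list(scorer.items_)
    predicted = [m.name for m in predicted_measures(
        DEFAULT_CATALOG if scorer.catalog is None else scorer.catalog)]
    predicted += [c for c in (*PROTEIN_COLUMNS, CORT_COLUMN) if c in cohort.columns]
    out = {}
    for grp in ("SAL", "VPA"):
        ids = cohort.loc[cohort["prenatal"] == grp, "animal_id"]
        Z = complete_rows(Zall.loc[ids], core)
        model = WardClusterer(n_clusters=k).fit(Z)
        sol = model.solution(scores=scores)
        prof = profile(sol, cohort[cohort["prenatal"] == grp], scores,
                       core_vars=core, predicted_vars=predicted)
        out[grp] = {
            "model": model,
            "solution": sol,
            "profiles": prof,
            "newick": to_newick(model.dendrogram_),
            "diagnostics": model.diagnostics(),
            # percent of the group in the two highest-scoring clusters
            "high_emotionality_percent": percent_of_group(
                int(prof.nlargest(min(2, k), "score_mean")["size"].sum()),
                int(prof["size"].sum()),
            ),
        }
    return out


def run_all(
    cohort: pd.DataFrame,
    out_dir: str | Path,
    seed: int | None = None,
    k: int = 4,
    catalog: Sequence[MeasureDefinition] = DEFAULT_CATALOG,
    cohort_meta: Mapping | None = None,
) -> dict:
    """Score -> stats -> cluster; write all outputs under ``out_dir``.

    Returns the aggregated report dict (also written to report.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = metadata(seed, dict(cohort_meta or {}, k=k, n=len(cohort)))

    scores, scorer = score_stage(cohort, catalog=catalog)
    write_table(scores.reset_index(), out_dir / "scores.csv", meta)
    write_json({"consistency": scorer.consistency_.to_dict()},
               out_dir / "consistency.json", meta)

    tests = stats_stage(cohort, scores, catalog=catalog)
    write_table(tests, out_dir / "stats.csv", meta)

    clusters = cluster_stage(cohort, scores, scorer, k=k)
    report: dict = {"consistency": scorer.consistency_.to_dict(), "clusters": {}}
    labels_rows = []
    for grp, res in clusters.items():
        (out_dir / f"dendrogram_{grp}.nwk").write_text(
            f"[{' '.join(f'{k2}={v}' for k2, v in meta.items())}]\n" + res["newick"] + "\n"
        )
        write_table(res["profiles"], out_dir / f"profiles_{grp}.csv", meta)
        for aid, lab in res["solution"].labels.items():
            labels_rows.append({"animal_id": aid, "prenatal": grp, "cluster": lab})
        report["clusters"][grp] = {
            "k": k,
            "sizes": res["profiles"].set_index("cluster")["size"].to_dict(),
            "percents": res["profiles"].set_index("cluster")["percent_of_group"].to_dict(),
            "profiles": res["profiles"].round(6).to_dict(orient="records"),
            "note": (
                "percents are nearest-integer and may sum to 100 +/- 1; "
                "floor rounding would differ for sizes like 4/53"
            ),
        }
    write_table(pd.DataFrame(labels_rows), out_dir / "cluster_labels.csv", meta)
    report["tests"] = tests.round(6).to_dict(orient="records")
    write_json(report, out_dir / "report.json", meta)
    return report


def simulate_stage(config, seed: int | None, out_path: str | Path) -> pd.DataFrame:
    from .simulate import generate

    cohort = generate(config, seed=seed)
    meta = metadata(seed if seed is not None else config.seed,
                    {"n_per_cell": {f"{a}-{b}": n for (a, b), n in config.n_per_cell.items()}})
    write_cohort(cohort, out_path, meta=meta)
    return cohort
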
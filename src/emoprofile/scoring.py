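"""Composite emotionality score.

Pipeline: z-transform each behavioral measure over the pooled cohort,
negate inverted scales so that larger values always mean higher
emotionality, search measure subsets for maximal internal consistency
(standardized Cronbach's alpha computed from the mean inter-item Pearson
correlation), and average the selected oriented z-scores per animal into
one composite score.

`EmotionalityScorer` packages the whole pipeline as a scikit-learn
transformer; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import DEFAULT_CATALOG, MeasureDefinition, candidate_measures

#: Minimum pairwise correlation below which a consistency result is flagged.
DEFAULT_MIN_R_FLOOR = 0.28


@dataclass(frozen=True)
class ConsistencyResult:
    """Internal consistency of a measure subset.

    Attributes
    ----------
    items : tuple of str
        Selected measure names, sorted.
    r_matrix : pandas.DataFrame
        Pairwise Pearson correlations of the (oriented) z-scores.
    r_bar : float
        Mean off-diagonal correlation.
    alpha : float
        Standardized Cronbach's alpha, ``k*r_bar / (1 + (k-1)*r_bar)``.
    min_item_total_r : float
        Smallest correlation between an item and the mean of the others.
    min_pairwise_r : float
        Smallest off-diagonal entry of ``r_matrix``.
    flipped : frozenset of str
        Items whose orientation was inverted relative to the input.
    """

    items: tuple[str, ...]
    r_matrix: pd.DataFrame
    r_bar: float
    alpha: float
    min_item_total_r: float
    min_pairwise_r: float
    flipped: frozenset = frozenset()

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "r_matrix": self.r_matrix.round(6).to_dict(),
            "r_bar": round(self.r_bar, 6),
            "alpha": round(self.alpha, 6),
            "min_item_total_r": round(self.min_item_total_r, 6),
            "min_pairwise_r": round(self.min_pairwise_r, 6),
            "flipped_items": sorted(self.flipped),
        }


def cronbach_alpha(r_bar: float, k: int) -> float:
    """Standardized Cronbach's alpha from the mean inter-item correlation.

    alpha = k * r_bar / (1 + (k - 1) * r_bar), defined for k >= 2 items
    and r_bar strictly above -1/(k-1) (at the boundary the average item
    covariance degenerates).
    """
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if not (-1.0 / (k - 1) < r_bar <= 1.0):
        raise ValueError(f"r_bar={r_bar} outside (-1/(k-1), 1] for k={k}")
    return k * r_bar / (1.0 + (k - 1) * r_bar)


def zscore(
    df: pd.DataFrame,
    measures: Sequence[MeasureDefinition] | Sequence[str],
    means: pd.Series | None = None,
    sds: pd.Series | None = None,
) -> pd.DataFrame:
    """Standardize measure columns over the pooled cohort and orient scales.

    Per column: subtract the mean and divide by the sample sd (ddof=1)
    computed over all animals with a value; missing cells stay missing.
    Columns flagged ``inverted`` in the catalog are negated *after*
    standardization, so positive z always reads as higher emotionality.
    Precomputed ``means``/``sds`` (e.g. from a training cohort) may be
    supplied.
    """
    defs = [m if isinstance(m, MeasureDefinition) else _lookup(m) for m in measures]
    out = {}
    for m in defs:
        col = pd.to_numeric(df[m.name], errors="coerce")
        if col.notna().sum() < 2:
            raise ValueError(f"measure {m.name!r} has fewer than 2 observed values")
        mu = float(means[m.name]) if means is not None else col.mean()
        sd = float(sds[m.name]) if sds is not None else col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"measure {m.name!r} has zero variance; cannot z-score")
        z = (col - mu) / sd
        out[m.name] = -z if m.inverted else z
    return pd.DataFrame(out, index=df.index)


def _lookup(name: str) -> MeasureDefinition:
    for m in DEFAULT_CATALOG:
        if m.name == name:
            return m
    return MeasureDefinition(name, unit="", inverted=False)


def _corr_pairwise(Z: pd.DataFrame, items: Sequence[str]) -> pd.DataFrame:
    sub = Z[list(items)]
    for a, b in itertools.combinations(items, 2):
        if (sub[a].notna() & sub[b].notna()).sum() < 3:
            raise ValueError(f"fewer than 3 pairwise-complete observations for ({a}, {b})")
    r = sub.corr(method="pearson", min_periods=3)
    bad = [
        (a, b)
        for a, b in itertools.combinations(items, 2)
        if not np.isfinite(r.loc[a, b])
    ]
    if bad:
        raise ValueError(f"undefined pairwise correlation for item pairs: {bad}")
    return r


def consistency(Z: pd.DataFrame, items: Sequence[str]) -> ConsistencyResult:
    """Pairwise-complete Pearson matrix, mean inter-item r, and alpha."""
    items = tuple(sorted(items))
    if len(items) < 2:
        raise ValueError("consistency requires at least 2 items")
    r = _corr_pairwise(Z, items)
    k = len(items)
    off = r.to_numpy()[~np.eye(k, dtype=bool)]
    r_bar = float(off.mean())
    item_total = []
    for it in items:
        rest = Z[[j for j in items if j != it]].mean(axis=1, skipna=True)
        item_total.append(float(Z[it].corr(rest)))
    return ConsistencyResult(
        items=items,
        r_matrix=r,
        r_bar=r_bar,
        alpha=cronbach_alpha(r_bar, k),
        min_item_total_r=float(min(item_total)),
        min_pairwise_r=float(off.min()),
    )


def _subset_alpha(R: np.ndarray, idx: tuple[int, ...], exhaustive_orient: bool = True):
    """Best orientation and alpha for one candidate subset.

    Works on the precomputed full correlation matrix: flipping item i maps
    R -> s s^T * R elementwise with s_i = -1. Maximizing alpha for fixed k
    is maximizing s^T R s. Exhaustive over 2^(k-1) sign patterns for small
    k, else iterative single-flips to a local optimum.
    """
    sub = R[np.ix_(idx, idx)]
    k = len(idx)
    if exhaustive_orient and k <= 14:
        best_s, best_q = None, -np.inf
        for bits in itertools.product((1.0, -1.0), repeat=k - 1):
            s = np.array((1.0,) + bits)
            q = float(s @ sub @ s)
            if q > best_q:
                best_q, best_s = q, s
        s = best_s
    else:
        s = np.ones(k)
        for _ in range(100):
            gains = (sub * np.outer(s, s)).sum(axis=1) - np.diag(sub)
            worst = int(np.argmin(gains))
            if gains[worst] >= 0:
                break
            s[worst] = -s[worst]
    oriented = sub * np.outer(s, s)
    r_bar = float((oriented.sum() - k) / (k * (k - 1)))
    if r_bar <= -1.0 / (k - 1):
        return s, r_bar, -np.inf
    return s, r_bar, cronbach_alpha(r_bar, k)


def select_items(
    Z: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    min_size: int = 3,
    min_r_floor: float = DEFAULT_MIN_R_FLOOR,
) -> ConsistencyResult:
    """Exhaustive search for the measure subset maximizing Cronbach's alpha.

    Every subset of size >= ``min_size`` is scored; for each subset both
    orientations of every item are considered, preferring the sign pattern
    that makes all item-rest correlations positive (it also maximizes
    alpha for the subset). Ties are broken toward the larger subset, then
    lexicographically by item names. The best subset is always returned,
    but a warning is raised when it has no real internal consistency:
    alpha not above zero, or a pairwise correlation below ``min_r_floor``.
    """
    if candidates is None:
        candidates = list(Z.columns)
    candidates = sorted(candidates)
    if len(candidates) > 20:
        raise ValueError("exhaustive subset search limited to 20 candidate measures")
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    R = _corr_pairwise(Z, candidates).to_numpy()
    best = None  # (alpha, size, names, signs, r_bar)
    for size in range(min_size, len(candidates) + 1):
        for idx in itertools.combinations(range(len(candidates)), size):
            s, r_bar, alpha = _subset_alpha(R, idx)
            names = tuple(candidates[i] for i in idx)
            key = (alpha, size, tuple(-ord(c) for c in ",".join(names)))
            if best is None or key > best[0]:
                best = (key, names, s, r_bar, alpha)
    _, names, signs, r_bar, alpha = best
    flipped = frozenset(n for n, s in zip(names, signs) if s < 0)
    Zo = Z[list(names)].copy()
    for n in flipped:
        Zo[n] = -Zo[n]
    res = consistency(Zo, names)
    if res.alpha <= 0 or res.min_pairwise_r < min_r_floor:
        warnings.warn(
            f"selected subset has weak internal consistency "
            f"(alpha={res.alpha:.3f}, min pairwise r={res.min_pairwise_r:.3f} "
            f"< floor {min_r_floor})"
        )
    return ConsistencyResult(
        items=res.items,
        r_matrix=res.r_matrix,
        r_bar=res.r_bar,
        alpha=res.alpha,
        min_item_total_r=res.min_item_total_r,
        min_pairwise_r=res.min_pairwise_r,
        flipped=flipped,
    )


def composite(
    Z: pd.DataFrame,
    items: Sequence[str],
    flipped: frozenset = frozenset(),
) -> pd.Series:
    """Per-animal emotionality score: mean of the oriented item z-values.

    An animal's score is defined only when at least ceil(k/2) of the k
    item values are observed; otherwise it is missing.
    """
    items = list(items)
    missing_cols = [i for i in items if i not in Z.columns]
    if missing_cols:
        raise ValueError(f"items not in z-matrix: {missing_cols}")
    sub = Z[items].copy()
    for n in flipped:
        sub[n] = -sub[n]
    need = math.ceil(len(items) / 2)
    score = sub.mean(axis=1, skipna=True)
    score[sub.notna().sum(axis=1) < need] = np.nan
    return score.rename("emotionality_score")


class EmotionalityScorer(BaseEstimator, TransformerMixin):
    """Composite emotionality score as a scikit-learn transformer.

    ``fit`` learns pooled-cohort standardization statistics, orients the
    scales, and (when ``items="auto"``) runs the exhaustive internal-
    consistency subset search. ``transform`` maps a cohort table to a
    single-column array of per-animal composite scores on the training
    scale.

    Parameters
    ----------
    catalog : sequence of MeasureDefinition, optional
        Measure catalog; defaults to the built-in one. Candidates for the
        subset search are its ``emotionality_candidate`` entries.
    items : "auto" or sequence of str
        Fixed item set, or ``"auto"`` to maximize Cronbach's alpha.
    min_size : int
        Smallest subset considered by the search.
    min_r_floor : float
        Pairwise-correlation floor below which the fitted result is
        flagged (``low_r_flag_``) with a warning.

    Attributes
    ----------
    items_ : tuple of str
        Selected measures.
    alpha_, r_bar_ : float
        Internal consistency of the selection.
    consistency_ : ConsistencyResult
    means_, sds_ : pandas.Series
        Pooled standardization statistics per candidate measure.
    """

    def __init__(
        self,
        catalog: Sequence[MeasureDefinition] | None = None,
        items: str | Sequence[str] = "auto",
        min_size: int = 3,
        min_r_floor: float = DEFAULT_MIN_R_FLOOR,
    ):
        self.catalog = catalog
        self.items = items
        self.min_size = min_size
        self.min_r_floor = min_r_floor

    def _defs(self) -> list[MeasureDefinition]:
        cat = DEFAULT_CATALOG if self.catalog is None else self.catalog
        return candidate_measures(cat)

    def fit(self, X: pd.DataFrame, y=None) -> "EmotionalityScorer":
        defs = self._defs()
        names = [m.name for m in defs]
        X = pd.DataFrame(X)
        self.means_ = pd.Series({n: pd.to_numeric(X[n], errors="coerce").mean() for n in names})
        self.sds_ = pd.Series(
            {n: pd.to_numeric(X[n], errors="coerce").std(ddof=1) for n in names}
        )
        Z = zscore(X, defs)
        if isinstance(self.items, str) and self.items == "auto":
            self.consistency_ = select_items(
                Z, names, min_size=self.min_size, min_r_floor=self.min_r_floor
            )
        else:
            self.consistency_ = consistency(Z, list(self.items))
        self.items_ = self.consistency_.items
        self.alpha_ = self.consistency_.alpha
        self.r_bar_ = self.consistency_.r_bar
        self.low_r_flag_ = self.consistency_.min_pairwise_r < self.min_r_floor
        if self.low_r_flag_:
            warnings.warn(
                f"minimum pairwise correlation {self.consistency_.min_pairwise_r:.3f} "
                f"below the {self.min_r_floor} floor"
            )
        self.n_features_in_ = len(names)
        return self

    def z_matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        """Oriented z-scores of the candidate measures on the training scale."""
        check_is_fitted(self, "items_")
        return zscore(pd.DataFrame(X), self._defs(), means=self.means_, sds=self.sds_)

    def score_frame(self, X: pd.DataFrame) -> pd.Series:
        """Composite scores as a named pandas Series (index preserved)."""
        Z = self.z_matrix(X)
        return composite(Z, self.items_, self.consistency_.flipped)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_frame(X).to_numpy().reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["emotionality_score"], dtype=object)
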
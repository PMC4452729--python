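# Methods

## The analysis in brief

The package analyzes cohorts from a 2×3 factorial design — prenatal
exposure (SAL, VPA) × rearing environment (ST, UE, PE) — with one row per
animal and named behavioral measure columns described by a catalog
(`emoprofile.catalog`). Three stages build on each other:

1. composite emotionality scoring (`emoprofile.scoring`),
2. group-level inference (`emoprofile.stats`),
3. per-group hierarchical clustering and profiling
   (`emoprofile.clustering`).

A synthetic cohort generator (`emoprofile.simulate`) supplies data with
the statistical structure the analysis assumes; it is first-class, tested
code, not a test fixture.

## Composite emotionality score

Each candidate measure is z-transformed over the **pooled cohort** (both
prenatal groups, all environments; sample sd, ddof = 1). Measures whose
raw scale runs opposite to emotionality (EPM open-arm time: more
exploration = less anxiety) are negated **after** standardization, per the
catalog's `inverted` flag. Pooled standardization is deliberate: the
composite is compared across design cells and the cluster profiles of the
two prenatal groups are read on one axis, which requires a common scale.
The fitted `EmotionalityScorer` stores the pooled means/sds, so new data
are mapped onto the training scale (standard transformer semantics).

Internal consistency uses the **standardized** Cronbach's α computed from
the mean off-diagonal Pearson correlation r̄ of k items,
α = k·r̄/(1 + (k−1)·r̄), rather than the covariance form — the inputs are
unit-variance z-scores, for which the two coincide in population, and the
standardized form is exact given a correlation matrix. Correlations are
pairwise-complete (per-variable missingness is expected in the
biochemical columns; a pair with fewer than 3 complete observations is an
error naming the pair).

`select_items` enumerates every subset of ≥ `min_size` candidates (the
catalog bounds candidates at 20, so the search stays exact) and, within a
subset, chooses item orientations maximizing α (equivalently sᵀRs over
sign vectors s; exhaustive up to k = 14, iterative single-flips beyond).
When a sign pattern making all item-rest correlations positive exists,
this is that pattern. Ties prefer the larger subset, then lexicographic
names. The winner is flagged (warning + `low_r_flag_`) when its weakest
pairwise correlation falls below 0.28, the floor reported for a sound
five-item composite, or when α ≤ 0.

The per-animal score is the mean of the oriented z-values over the
selected items, defined only when at least ⌈k/2⌉ items are observed —
averaging fewer than half the items would silently change what the score
measures.

## Group inference

* **Two-way ANOVA.** Type III sums of squares with sum-to-zero factor
  coding, computed by explicit least-squares model comparison (drop the
  term's columns from the full interaction model; ΔRSS is the term SS).
  Type III with deviation coding is the appropriate choice for this
  mildly unbalanced design (one cell has n = 17) when main effects are
  reported alongside an interaction. The implementation is plain
  numpy `lstsq` — one fit costs ~1 ms, which keeps the 2,000-replicate
  null-calibration test cheap — and is verified in the test suite against
  `statsmodels.anova_lm(typ=3)` with `C(·, Sum)` coding.
* **Post-hoc comparisons** are independent two-sample t-tests of SAL vs
  VPA within each environment (not pooled-MSE contrasts), Bonferroni
  multiplier m = 3. The Welch (unequal-variance, Satterthwaite df)
  variant is triggered automatically when the two-sided variance F-test
  (F = s₁²/s₂², p = 2·min(tails) capped at 1) rejects at 0.05 — the same
  decision rule a careful analyst applies by hand. Per-pair error terms
  are used because group variances genuinely differ between cells here;
  a pooled error term would contradict the Welch corrections.
* **Exact tests.** Perseveration (re-entering the same Y-maze arm on two
  consecutive trials) is a rare binary event: ~4% of control and ~19% of
  exposed animals. Pooled counts use Fisher's exact test with the
  two-sided minimum-likelihood rule (sum of same-margin tables with point
  probability ≤ observed) — the dominant software convention, delegated
  to `scipy.stats.fisher_exact` and verified against full enumeration.
  Per-environment counts (n = 18 per group) use **Barnard's
  unconditional test**, implemented in-package: the statistic is the
  pooled-proportion Wald score T, and the p-value is the supremum over
  the nuisance success probability π on a uniform grid (default step
  0.001) of the probability of all tables with |T| ≥ |T_obs| under
  independent binomials. The argmax π is reported alongside p and T
  because the nuisance value is part of how such results are printed.
  The unconditional test is preferred at these sample sizes because
  conditioning on the observed margin discards most of the information
  when events are rare. `scipy.stats.barnard_exact` (which does not
  expose the argmax π) serves as an independent cross-check in tests.
* **Spearman's ρ** (mean ranks for ties, pairwise-complete, n ≥ 4) links
  the emotionality score to protein immunoreactivity per prenatal group;
  one-way ANOVA screens environment effects on each protein.

## Clustering and profiles

Animals are clustered **separately per prenatal group** but on
pooled-cohort z-scores of the selected items (never re-standardized
within group), so the two dendrogram sets are comparable on one scale.
Distances are squared Euclidean; linkage is Ward's minimum-variance
criterion via the Lance–Williams recurrence. **Merge heights are the raw
within-cluster SS increase of each merge** (no square-root transform):
with D = 2·ΔSS initialized at squared distances, the recurrence
d(k, i∪j) = [(nᵢ+nₖ)d(ik) + (nⱼ+nₖ)d(jk) − nₖ·d(ij)] / (nᵢ+nⱼ+nₖ)
is exact, and heights then sum to the total SS of the clustered points
(asserted as a conservation property in tests). This convention is
recorded in output metadata because common toolkits differ — scipy's
Ward heights are √(2·ΔSS); the test suite checks the two agree under
that monotone transform. Merge ties break toward the lowest pair index
after sorting animal ids, making schedules deterministic across
platforms. Animals missing any core measure are excluded with a logged
warning rather than imputed.

A cut at k undoes the last k−1 merges; clusters are labeled I..k by
ascending mean composite score. k defaults to 4 but is a configuration
knob, and `homogeneity_diagnostics` always reports, for each k, the merge
height a cut avoids and its ratio to the last height it keeps; ratios
above 3 are flagged as dominant gaps (unstructured data stays below
~2.5), supporting a parsimony-based choice of k.

Profiles report, per cluster: size and nearest-integer percent of the
group (rounded percents can sum to 100 ± 1; for sizes like 4/53 = 7.5%
nearest-integer gives 8 where floor rounding would give 7 — the report
notes this convention), mean ± sem of the composite score and each core
measure, mean ± sem of each held-out variable with pairwise deletion
(sociability, nociception, proteins, corticosterone), and the ST/UE/PE
composition. Cluster-to-cluster hypothesis tests are deliberately out of
scope — with cluster sizes this uneven the comparisons are qualitative.

Dendrograms are exported as Newick with branch lengths defined by merge
heights (a child's branch = parent height − child height), so root-to-
leaf depth equals the top merge's SS increase.

## Synthetic cohort generator

The generator emulates the study conditions the analysis was built for:

* **Design:** n = 18 per cell, 17 in VPA-PE (107 animals, 6 cells).
* **Emotionality measures:** per animal, a 5-vector from a multivariate
  normal with compound-symmetry correlation r (default 0.335) on the
  oriented scale, mapped to raw scales by cell-specific means/sds.
  Compound symmetry is the simplest structure consistent with a single
  reported mean correlation plus a floor. The per-cell means are anchored
  to a programmed emotionality level ordering VPA-ST highest (0.8),
  VPA-UE 0.6, SAL-UE/PE 0.1, SAL-ST −0.5, VPA-PE lowest (−0.6) —
  defaults chosen to reproduce the qualitative cell ordering, not any
  printed group mean (raw-scale cell statistics are not published).
  Baselines sit ≥ 2.5 sd from range bounds (freezing ∈ [0,100], times
  ≥ 0) so that clamping — chosen over resampling to keep per-seed
  determinism — alters < 1% of draws; heavier clamping is logged.
* **Variance heterogeneity:** VPA-PE has a 2× sd (4× variance) on EPM
  open-arm time and on social preference relative to SAL-PE, mirroring
  the reported variance ratios around 4.
* **Perseveration:** Bernoulli per prenatal group, defaults 2/54 (SAL)
  and 10/53 (VPA) — the published pooled counts.
* **Biochemistry:** protein IR and corticosterone are linear in the
  animal's latent emotionality deviation (the mean of its 5 correlated
  z-deviations) plus noise, with opposite coupling signs in SAL vs VPA;
  raw band volumes carry multiplicative assay-batch gains (3 batches,
  counterbalanced), which the within-batch SAL-ST reference
  normalization (`normalize_ir`) removes.
* **Randomness:** one stream per cohort, split per animal by counter
  (`default_rng([seed, index])`), so adding a variable never perturbs
  earlier animals' draws.

What the generator does **not** emulate: litter effects (siblings were
distributed across environments and animals are treated as independent),
within-session time courses, floor/ceiling measurement artifacts beyond
simple clamping, and any non-Gaussian shape of real behavioral
distributions. Passing tests therefore demonstrate that the pipeline
recovers known structure of this idealized kind, not that it would be
robust to clustered or heavy-tailed real data.

## Numerical conventions and degenerate inputs

* z-scoring uses ddof = 1; zero-variance columns are hard errors naming
  the measure.
* α is defined for k ≥ 2 and r̄ ∈ (−1/(k−1), 1]; the boundary is an
  error, not a NaN.
* Preference index = social/(social+object) sniffing time; a zero total
  is a flagged missing value, not 0 or 0.5.
* Fisher with a zero margin returns p = 1 with a warning; Barnard with
  no successes in either group returns T = 0, p = 1.
* Within-batch IR normalization with no usable reference animals flags
  the whole batch missing and logs a warning.
* All file outputs carry `# key: value` metadata headers (tool version,
  seed, config hash) and are byte-deterministic at fixed seed.

## Problem sizes used in the test suite

Property and calibration tests run at sizes chosen to make sampling error
negligible relative to the asserted tolerances while keeping the suite
quick: correlation-recovery checks at n = 5,000–10,000 per cell,
ANOVA type-I calibration over 2,000 null replicates at the study's exact
design (rejection rate asserted within [0.03, 0.07] at α = 0.05), the
interaction sign-pattern power check over 500 replicates at n = 18/cell
(≥ 80% recovery required), and exhaustive oracle sweeps (Ward vs a
coordinate-based greedy SS oracle on 100 random 5–8 point instances;
Fisher vs full enumeration for group sizes ≤ 12; Barnard vs a 1e-4
nuisance grid on 20 tables; Type III ANOVA vs statsmodels on 50 random
unbalanced datasets).

## Known limitations

* The exhaustive consistency search is exponential in the candidate
  count; the catalog caps it at 20 candidates (the intended use has ≤ 9).
* No mixed models or litter-level random effects; no repeated-measures
  ANOVA across fear-conditioning sessions (each session is tested
  separately).
* Barnard's test uses the Wald-score variant; other score functions
  (e.g. Boschloo) give slightly different p-values.
* Ward clustering is O(n³) in the plain implementation used here —
  irrelevant at cohort sizes of ~50 per group, unsuitable for thousands.
* Cluster labels I..k are ordered by mean composite score; with near-tied
  cluster means the ordering can be unstable under resampling even though
  it is deterministic for a fixed dataset.
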
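# Methods

## Scope and model

`ricotype` reconstructs a multivariate cooking-quality classification for an
indica rice diversity panel (211 accessions, three quality clusters of
114/70/27). The pipeline is: instrument-curve feature extraction → 25-variable
panel assembly → correlation-redundancy pruning to 19 variables → Ward
clustering (k = 3) → forward-AIC multinomial logistic regression →
likelihood-ratio tests and pseudo-R² → per-cluster random-forest permutation
importance → descriptive sensory summaries. Every stage consumes inputs the
synthetic-data module can generate, so the analysis is fully reproducible
offline.

## Curve landmark extraction

**Rheometry.** A sweep holds time (min), temperature (one heating then one
cooling ramp, nominally 35→95→35 °C at 4 °C min⁻¹) and the storage and loss
moduli G′, G″ (kPa). The gel point is the first crossing of
tan δ = G″/G′ through 1 on the heating ramp, located by linear interpolation
between the bracketing samples; a trace with no strict crossing (including the
degenerate G′ ≡ G″ case) raises a "no gel point" error. G′max and G″max are
trace maxima (earliest sample on ties — determinism), G′trough the G′ minimum
after G′max ("no trough" flag when G′max is the final sample). Slopes are mean
rates of change between landmarks: S1 (S3) from the gel point to G′max
(G″max); S2 from G′max to G′trough; S4 from G″max to the level-off point.
"Level-off" has no published threshold; it is defined here as the first sample
after G″max with |dG″/dt| < `level_off_eps` (default 0.05 kPa min⁻¹,
configurable). S2 and S4 are stored signed and reported as magnitudes (the
sign encodes direction only). tan δ at G′max is G″/G′ at the G′max sample, so
tan δ · G′max = G″ at G′max holds exactly by construction. Whether the G″max
search should be restricted to the heating ramp is not documented anywhere we
know of; a `gmax_scope` switch exposes both, defaulting to the global maximum.

**RVA pasting.** PV is the maximum viscosity during the heating + holding
stages (cooling onset detected from the temperature plateau), PT its time, TV
the post-peak minimum, FV the final sample. BD/SB/LO are computed from
PV/TV/FV, so the identities BD = PV − TV, SB = FV − PV, LO = FV − TV = BD + SB
hold to machine precision for every input. The pasting temperature is the
temperature at the first sample where dV/dt exceeds `ptemp_rate`
(default 0.10 viscosity units min⁻¹); instrument software uses a proprietary
set point, so the threshold is configurable and recorded with every run.
Viscosity units are instrument-native and carried as opaque metadata — no
conversion is attempted.

**TPA.** A valid two-compression trace has two positive force lobes. Hardness
is the first lobe's peak force; cohesiveness the trapezoidal area ratio
lobe 2 / lobe 1; adhesiveness the magnitude of the negative (pull-off) lobe
area between compressions, with the magnitude convention flagged;
springiness the ratio T2/T1 of downstroke durations (lobe start to apex),
time and probe travel being proportional at constant test speed.

**Smoothing.** All extractors optionally apply a centered moving average
before landmark detection (`smoothing_window`, default 5 samples; window 1
disables it, the appropriate setting for noiseless synthetic fixtures).
Raw-trace landmark detectors are unstable under instrument noise; a symmetric
window preserves landmark locations to within half a window.

## Panel assembly and pruning

Crude protein is 5.95 × %Kjeldahl-N. AC classes use the conventional five
bins (waxy 0–2, very low 3–9, low 10–19, intermediate 20–25, high > 25 %);
the printed bin edges leave gaps, closed here with half-open bins cut at
2.5/9.5/19.5 and 25.0 assigned to intermediate (the 20–25 bin is inclusive).
GT classes: low < 67 °C, high ≥ 74 °C, the unassigned 67–68 and 73–74 °C
intervals resolved into intermediate for totality; edges configurable.
Replicates (triplicate rheometry, 3 × 3 TPA) are averaged arithmetically per
sample with counts recorded; missing cells fail fast naming sample and
variable.

Pruning computes all-pairs Pearson r (two-sided t-test p-values; stars at
p < 0.1/0.05/0.01) and flags |r| > 0.75. Two drop policies: `"paper"` pins the
six-variable set the source study removed (TV, FV, pasting temperature,
temperature at gel point, G″ at G′max, temperature at G′max — the complement
of the 19 profiled variables, which also resolves the study's ambiguous
removed-list typography; peak time is retained); `"greedy"` iteratively drops,
from the worst flagged pair, the member with the larger mean absolute
correlation. Threshold 1.0 makes pruning the identity on any panel without an
exactly collinear pair.

## Clustering

Ward minimum-variance linkage on Euclidean distances via
`scipy.cluster.hierarchy.linkage(method="ward")` — the squared-distance update
convention (ward.D2 semantics). Variables are z-scored first by default: the
panel mixes kPa-scale moduli with ratio-scale texture attributes, and both
settings were compared on synthetic panels before pinning (standardized Ward
recovers generating labels at median ARI ≈ 0.67 vs ≈ 0.16 raw-scale).
Clusters are renumbered 1..k by decreasing size, so cluster 1 is always the
largest. Profiles report per-cluster mean and sample SD (n − 1 denominator;
absent for singletons).

## Classification

The multinomial logit assigns sample i the score βₖ·Xᵢ per non-reference
cluster k (reference cluster 1 scores 0) and softmax class probabilities.
Fitting is delegated to `statsmodels.MNLogit` with a Newton solver
(tol 1e-8 on the gradient, 500 iterations), falling back to
BFGS/L-BFGS/Nelder-Mead when the Hessian is singular or estimates go
non-finite; standard errors come from the observed information. Predictors
are used raw (unstandardised), matching the magnitude pattern of the source
coefficient table. Diverging coefficients (|β| > 25) or non-convergence emit
a separation warning; the capped fit is still returned. Rank-deficient
designs are rejected naming the collinear columns.

Forward selection starts from the intercept-only model, at each step adding
the variable minimising AIC = deviance + 2 · (free parameters), ties broken
toward the earlier column; it stops when no addition lowers AIC, so the
result never has higher AIC than the null model. Likelihood-ratio tests refit
without one variable (χ² = deviance difference, df = number of non-reference
clusters, here 2); a refit that fails to converge is flagged (NaN) rather
than fabricated. Pseudo-R²: McFadden 1 − D_f/D₀; Cox & Snell 1 − exp(−χ²/n);
Cragg & Uhler (Nagelkerke) rescales Cox & Snell by its maximum
1 − exp(−D₀/n). For the study's printed deviances (405.87 → 66.20, n = 211)
these evaluate to 0.84/0.80/0.94, which the worked-example test asserts.
Accuracy is resubstitution accuracy (no cross-validation, matching the source
analysis).

**Forest importance.** 500 CART trees on bootstrap resamples with 3 candidate
variables per split, built as a bagging ensemble of
`DecisionTreeClassifier(max_features=3)` — the same algorithm as a random
forest, chosen because the bagging API exposes per-tree in-bag indices
publicly, which the out-of-bag bookkeeping needs. Per tree and variable, the
variable's values are permuted among that tree's OOB samples and the
per-class and overall accuracy drops recorded; importances are tree-averaged
and standardized by their standard error over trees (the convention of
standard forest importance output). Mean-decrease-in-impurity is deliberately
not used — the method of record is permutation importance. The forest seed
defaults to 20180245 and is recorded in outputs; results are bit-for-bit
reproducible under a fixed seed. The RF runs on the MLR-selected variable
set (the source text is ambiguous between 9 and 10 variables; the selected
set is used as given).

## Sensory summaries

Scores are intensities in mm on a 150-mm line scale over a closed 13-term
texture lexicon; values outside [0, 150] or unknown attributes are rejected.
Panelist scores are averaged per sample first; cluster mean ± SD is then
taken over sample-level means — with five samples per cluster this matches
the dispersion scale of the source summary table, which is consistent with
sample-level (not panelist-level) SDs. The standard sample served across
sessions is carried as metadata and excluded from summaries. Cluster
comparisons are descriptive (ordered means and gaps); no inferential test is
attached because none is defined for this design.

## Synthetic data: what it emulates and what it does not

**Curves.** Generators plant landmarks (gel temperature, G′max and its
temperature, G′trough, G″max / PV, TV, FV, PT / lobe areas, peaks, T1, T2)
and build piecewise-monotone PCHIP traces through them, so planted extrema
are exact and tan δ crosses 1 exactly once on heating (before the gel time
G′ is G″ times a monotone ratio rising to 1). Optional additive Gaussian
noise; all generators are pure functions of (spec, seed). Noiseless
extraction recovers every planted landmark within one sampling interval —
the tests assert this. The shapes are idealised: real traces carry
autocorrelated instrument noise, evaporation drift and baseline wander that
these generators do not model, so passing tests demonstrate correctness of
the landmark definitions, not robustness to every instrument artefact.

**Panels.** Per cluster, variables are drawn from a multivariate normal with
the published per-cluster means/SDs (sizes 114/70/27). By default the 19
retained variables are conditionally independent within a cluster: the
study's flagged (|r| > 0.75) correlation structure involves only the six
redundant variables, which are generated as noisy linear functions of their
parents (TV = PV − BD, FV = PV + SB, pasting temperature and gel-point
temperature from GT, G″ at G′max as G′max · tan δ, temperature at G′max
declining in G′max). The noise SDs are set in closed form so the panel-wide
correlations land near the printed values (r(TV, PV) ≈ 0.88,
r(PTemp, GT) ≈ 0.82, r(temp at G′max, G′max) ≈ −0.79). An optional
moderate within-cluster correlation set patterned on the printed Pearson
matrix is available but not default; measured on synthetic panels it lowers
Ward label recovery (median ARI 0.36 vs 0.67). A nearest-PSD repair
(eigenvalue clipping) is applied to any user-supplied correlation pattern
and its Frobenius distance reported.

A known, deliberate limitation: cluster labels in the real study are
*defined* by the Ward cut of the real panel, so the printed cluster sizes are
recovered exactly there by construction. Resampling Gaussians from the
printed within-cluster moments discards whatever geometry Ward exploited;
the generating mixture remains highly separable to a covariance-aware
(quadratic) classifier — its Monte-Carlo Bayes-optimal accuracy is ≈ 97.7 % —
but Ward's spherical geometry recovers the generating labels only at median
ARI ≈ 0.67, and per-cluster importance patterns shift accordingly (setback
ties amylose as a cluster-3 separator at these moments). Tests that
encode the stricter published recovery levels are expected to fail under
this generator and are retained unweakened.

**Sensory.** Sample-level attribute means are drawn from the per-cluster
summary moments, panelist replicates add truncated-normal noise (resampling
into [0, 150] rather than clipping, keeping moments interpretable; default
panelist SD 6 mm, a typical trained-panel repeatability scale).

**End-to-end study.** `gen_cooking_study` draws per-sample landmark sets by
jittering three well-separated cluster archetypes (4 % relative SD) and emits
one curve triple per sample; the full loop — extract → panel → Ward →
forward-AIC logit — reaches ≥ 90 % median accuracy against the generating
labels over 20 seeds, demonstrating every stage end to end on synthetic data.

## Problem sizes and numerics

Default test and acceptance runs use the study-scale panel (n = 211, 19–25
variables), 20-seed Monte-Carlo medians for recovery properties, 200
simulations for the LR type-I check (n = 300 each), n = 2000 for coefficient
recovery, and a 40-sample miniature study for the curve loop — sizes chosen
to give stable Monte-Carlo estimates at interactive runtimes. Presentation
tables are rounded to 2 d.p.; JSON outputs keep full precision, and every
output carries a hash of the resolved configuration.
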
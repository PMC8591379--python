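# Methods

## Model

Each acoustic response (MinDF, MaxDF, MeanDF, RangeDF; all in Hz) is
regressed on body mass in a log-log phylogenetic GLS:

    y = X β + ε,   ε ~ N(0, σ² V(θ)),

with `y = log10(response)`, `X = [1, log10(mass_g)]` and `V(θ)` an
among-species covariance/correlation structure derived from a rooted
phylogeny with branch lengths:

* **BM** — `V[i,j]` is the root-to-MRCA path length (tip variances equal
  root-to-tip depth).  No free parameter.
* **BM + Pagel's λ** — BM with off-diagonal entries multiplied by
  λ ∈ [0, 1]; λ = 0 is phylogenetic independence, λ = 1 pure BM.
* **BM + Grafen's ρ** — node heights derived from topology only
  (`(n_descendants − 1)/(n − 1)`, tips 0, root 1), node depths `1 − h`
  raised to the power ρ ∈ (10⁻⁴, 10]; tip variances are 1 and the scale is
  absorbed by σ².  Because the heights are topological, branch lengths do
  not enter this structure at all — this is deliberate and loud: on
  non-ultrametric trees the Grafen structure is insensitive to rate
  variation among lineages.
* **OU, fixed α** — correlation `exp(−α d_ij)` with `d_ij` the patristic
  distance, at α ∈ {0.1, 0.5, 1, 10} by default.  α is interpreted in the
  tree's own depth units; the tree is *not* rescaled to unit depth first,
  so the same α means different things on trees of different height.  α is
  never estimated (on a fixed consensus tree the stabilizing-selection
  strength is not identifiable in this design), hence one candidate model
  per fixed value.

Estimation is GLS via Cholesky whitening.  β̂ is the usual
`(X'V⁻¹X)⁻¹X'V⁻¹y`; residuals passed downstream are **response-scale**
(`y − Xβ̂`, log₁₀ Hz), not whitened — the outlier rule is meant to measure
deviation from the allometric line in interpretable units.  λ and ρ are
profiled by bounded Brent search (tolerance 1e−8, no randomness) on the
REML criterion, which includes the `−½ log|X'V⁻¹X|` term.  Model selection
uses AICc on REML log-likelihoods; this is legitimate here because every
candidate shares the same fixed-effect design.  The parameter count is
k = 2 coefficients + 1 (σ²) + 1 if λ or ρ was profiled.  Exact AICc ties
break toward fewer parameters, then BM < BM+λ < BM+ρ < OU.  Slope
significance is a Wald χ² (1 df) on an ML refit with the phylogenetic
parameter fixed at its REML estimate; for a single-predictor GLS this is
exactly the ANOVA of the selected model.  The Wald reference is
asymptotic: at n ≲ 50 it is mildly anticonservative (the test suite
calibrates it at n = 150, where the measured size is within [0.03, 0.07]).

## Outlier rule and taxonomy

A species is an outlier for a response when
`|r − median(r)| > t · b · MAD`, with threshold `t = 2.5` and the normal
consistency constant `b = 1.4826` (both configurable; `b = 1` gives the
uncorrected variant, and median-centering can be disabled).  When MAD = 0
(more than half the residuals identical) the rule degenerates; the
implementation warns and flags exactly the residuals differing from the
median.  Flagged species are marked U (residual > 0) or D (< 0), per
response independently — four separate regressions, four separate residual
vectors.

Outlier species are assigned one category: 1 = VPL with only U marks,
2 = non-VPL only D, 3 = VPL only D, 4 = non-VPL only U, 5 = VPL with both.
A non-VPL species with mixed marks has no published category; it receives
the documented sentinel 6 rather than being forced into category 5, which
is defined for VPL species only.

Association between VPL membership and outlier status is tested with
Barnard's unconditional exact test: ordering statistic is the pooled
two-proportion score
`z = (p̂₂ − p̂₁) / sqrt(p̂(1−p̂)(1/n₁+1/n₂))` (row 1 = VPL, so an outlier
excess among VPL species gives negative z), and the two-tailed p-value is
the maximum over a uniform open 200-point grid of the nuisance success
probability of `P(|Z| ≥ |z_obs|)` under independent binomials.  The grid
maximum is stable to three decimals against a 2000-point grid on all test
tables, and matches a brute-force enumeration oracle to 1e−10 at small
margins.  Residual distributions are compared with a two-tailed
Mann–Whitney U (W = pairs won by the first sample + half the ties, so
`W + W′ = n₁n₂`): exact enumeration of the null U distribution when
`n₁n₂ ≤ 400` and the pooled data are tie-free, otherwise a normal
approximation with tie and continuity corrections.  Raw "size-corrected"
comparisons divide each species' frequency by its body mass (Hz g⁻¹).

## Consensus tree and input handling

Multi-tree Newick inputs are reduced to a consensus-edge tree:
majority-rule over clades (> 50%, trivial clades always kept), each
retained clade's branch length the arithmetic mean over the input trees
containing that clade.  For identical input topologies this is exact
edge-wise averaging; a single input tree passes through unchanged.
Pruning to the analysis taxon set preserves pairwise patristic distances
exactly (degree-2 nodes are suppressed with summed lengths).  Species
names match after underscore/space normalization; any mismatch is reported
in full, never silently dropped.  All log transforms are base-10 (slopes
are base-invariant when both axes share a base; intercepts are reported
base-10).  A frequency range of zero has no logarithm: such species are
excluded from the RangeDF regression with a warning, unless a positive
offset is configured.

## Synthetic data

`SimulationConfig` defaults describe the emulated study conditions:
164 species on a unit-depth Yule tree; log₁₀ mass uniform on [0.5, 7.5]
(≈ 3 g to 30 t), exogenous to the phylogeny by default (an option
correlates it with the tree for stress tests); MinDF slope −0.37 and
intercept 2.7 log₁₀ Hz; residual Brownian rate σ² = 0.04 (marginal s.d.
0.2 log₁₀ Hz) attenuated by λ_true = 0.8; four disjoint monophyletic VPL
clades totalling ≈ 58/164 of tips.  RangeDF is simulated on the log scale
(slope −0.07, intercept 2.5) and MaxDF = MinDF + Range, so
MaxDF > MinDF > 0 holds by construction.  Directional VPL deviations are
injected as mean shifts `delta` (MinDF) and `delta_range` (RangeDF) in
log₁₀ Hz; the truth record stores every parameter, clade membership and
per-tip deviation.  What the generator does *not* emulate: realistic
mammal body-mass or frequency distributions, heterogeneous per-species
deviation sizes, measurement error, and within-clade variation in VPL
status.  Passing tests therefore validate the machinery (estimation,
calling, testing) under the assumed model, not biological conclusions.

## Validation conditions and known limitations

* **Null calibration** (delta = 0) is run with λ_true = 0, i.e.
  exchangeable residuals.  This is deliberate: with phylogenetically
  correlated residuals the VPL/non-VPL group comparisons are
  pseudoreplicated (whole clades share noise), and the signed-residual
  Mann–Whitney p-values are grossly non-uniform under the null (measured
  KS-vs-uniform p ≈ 0 at λ_true = 0.8 versus 0.72 at λ_true = 0 over 200
  replicates).  This anticonservatism is a property of testing raw
  residuals from any phylogenetic regression, not of this implementation.
* **The pipeline's outlier-association test is conservative under a clean
  null**: the MAD rule flags only ~1–2% of species, and Barnard's exact
  test on the resulting sparse 2×2 tables rejects at well under the
  nominal rate (measured type-I 0.015 at α = 0.05, 200 replicates).
  Interpreting a non-significant association as evidence of no effect is
  therefore not supported at these outlier counts.
* **MAD masking bounds detection recall at high contamination.**  With
  ≈ 35% of species shifted upward by a common +1.0 log₁₀ Hz, the
  contaminated MAD inflates the cutoff to ≈ 1.3–1.4 log₁₀ Hz while the
  fitted intercept absorbs ≈ 0.35 of the shift; mean per-tip recall of
  the injected outliers is ≈ 0.1–0.3, not ≳ 0.8.  High recall under this
  rule requires either a smaller outlying fraction (≲ 10%) or
  heterogeneous deviations (as real data have).  The direction of the
  injected deviation is nonetheless recovered essentially always (mean
  signed VPL residual positive in ≥ 95% of replicates).
* Degenerate inputs: non-PD covariance matrices raise (an explicit
  1e−10 diagonal jitter flag exists in `gls_fit`); simulated Yule trees
  extend pendant edges past the terminal speciation so sister tips are
  never identical; a residual of exactly 0 can never be flagged (asserted).

## Problem sizes used by the test suite

Chosen to exercise the claims at the study's own scale: λ/slope recovery
on 100 profiled fits at n = 164; null calibration on 200 full pipeline
runs (MinDF only); power runs on 20 replicates; exact-test oracles at
margins ≤ 10 and rank enumerations of C(9,4) arrangements.  The whole
suite runs in a few minutes on one CPU.
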
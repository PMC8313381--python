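# Methods

## Study design and data scales

The package targets probe × sample methylation matrices from designs with
three tissue groups (ATM, CAM, NTM) and very few samples per group, each
sample additionally labelled male or female. Analysis is done on M-values,
the log2-odds transform of the beta-value:

* beta = max(M,0) / (max(M,0) + max(U,0) + offset), offset 100 by default —
  the proportion-scale methylation level computed from methylated (M) and
  unmethylated (U) allele intensities; always in [0, 1).
* M-value = log2(beta / (1 − beta)); 0 means half-methylated. Beta-values of
  exactly 0 or 1 (possible in user-supplied files, never produced by the
  offset formula) are clipped to [1e-6, 1 − 1e-6] with a warning before the
  logit; the alternative (hard error) is available via `clip=False`.
* Hypo-/hypermethylation calls use beta < 0.2 / beta > 0.8, with strict
  inequalities, so boundary values are "intermediate".

Numerically, the beta ↔ M round trip is exact to 1e-12 for |M| ≲ 12; beyond
that the spacing of floating-point numbers near beta = 0 or 1 dominates
(the error grows like eps · 2^|M|), which is far outside the range of real
methylation data.

## Pre-filtering

Features with any missing value are dropped. Each remaining feature is
tested with a classical one-way ANOVA across the three tissue types,
pooling sexes (sex enters only the downstream model); features with
p < 0.05 (strict) are retained. Degenerate rows are flagged: zero
within-group variance with non-zero between-group variance gives p = 0;
a constant row gives p = 1. The filter is idempotent and, under a global
null, retains a fraction of features converging to alpha.

## The trajectory mixture model

For probe j, stratum s ∈ {male, female} and sample i, with CAM the
reference level and x₁/x₂ the ATM/NTM indicators:

y_jsi = a_js + x_si1 b_js1 + x_si2 b_js2 + e, e ~ N(0, σ_h²), h = z_js.

The nine clusters correspond to the sign pairs of (b₁, b₂) under the
convention that b₁ > 0 means the level *falls* from ATM to CAM ("Down"
first segment) and b₂ > 0 means it *rises* from CAM to NTM ("Up" second
segment). The enumeration is second-segment sign major: DownUp, FlatUp,
UpUp, DownFlat, FlatFlat, UpFlat, DownDown, FlatDown, UpDown.

Priors and parameterisation:

* **Slopes** are probe-specific. A flat coordinate is a point mass at 0; a
  nonzero-sign coordinate has a half-normal prior truncated to its sign
  with cluster-level precision τ_sh ~ Gamma(shape 7, rate 5), prior mean
  1.4. The cluster-level τ adaptively shrinks all member probes' slopes
  toward a common scale. Early in development the slopes were cluster-level
  (one b_sh shared by all member probes); that variant proved unidentifiable
  in practice — a sign-constrained cluster whose slope drifts toward 0 can
  imitate the flat cluster arbitrarily well, and with conditional-likelihood
  membership updates the chain settled in states where a near-zero "Down"
  component absorbed all truly flat probes. Probe-level slopes with the
  marginalised membership update below remove that failure mode and match
  how real effect sizes vary from probe to probe.
* **Intercepts** a_js ~ N(m_js, 10) with m_js the probe's stratum mean — a
  deliberately weak prior centred on the data; cluster-indexed intercepts
  would be unidentifiable with one or two samples per design cell.
* **Noise** σ_h² ~ Inverse-Gamma(2, b0) per cluster, pooled across strata
  and probes within the cluster, with a hierarchical rate
  b0 ~ Gamma(2, 2) updated from all nine clusters. The hierarchical rate
  keeps momentarily empty clusters' variances on the scale of the data; a
  fixed rate left empty clusters with inflated variances that acted as
  one-way traps for membership moves.
* **Weights** π_s ~ Dirichlet(1,…,1) per stratum; memberships are
  independent across strata given the weights, so the 81 pattern
  probabilities arise from the joint empirical frequency of the
  (male, female) membership pair. A joint Dirichlet over the 81 pairs is a
  possible extension; the per-stratum form keeps the two strata's updates
  symmetric and vectorisable.

### Gibbs sampler

Per sweep, in order: π_s | z; the blocked pair (z_js, b_js); a_js; τ_sh;
σ_h²; b0. The membership draw uses the component likelihood with the
probe's slopes integrated out analytically: for a free coordinate with n
informative samples, partial residual sum S, precision P = n/σ_h² + τ_sh
and posterior mean μ* = (S/σ_h²)/P, the marginal contributes

0.5 μ*² P + 0.5 log(τ_sh/P) + log 2 + log Φ(g μ* √P),

g being the coordinate's sign. The 0.5·log(τ/P) term is the Occam factor
that distinguishes a flat (point-mass) coordinate from a sign-constrained
coordinate near zero; without it the two are indistinguishable at the
likelihood level. Slopes are redrawn immediately after z from their
truncated-normal full conditionals (a valid blocked update), so sign
constraints hold by construction at every draw. Empty components refresh
τ (and their slopes, implicitly) from the prior, keeping the chain
irreducible. Memberships are sampled by Gumbel-max on the log-weights;
truncated normals are drawn through `scipy.stats.truncnorm`, which is
tail-stable. No thinning is applied.

Initialisation is deterministic from the data: per probe and stratum, the
segment estimates (ATM mean − CAM mean, NTM mean − CAM mean) are
thresholded at ±0.3 to pick a starting cluster, slopes start at the
sign-clipped estimates, τ at its prior mean and σ² at the pooled residual
variance. All randomness flows from one `numpy` Generator seeded by the
config, so identical inputs and seed give bit-identical posteriors.

### Selection

Retained draws are tabulated into per-probe 81-pattern frequencies. The
null probability p0 is the FlatFlat-FlatFlat entry. **Bayesian q-values**
are cumulative means over the ascending-sorted p0 — the estimated Bayesian
FDR incurred by calling every probe up to that rank — with ties sharing the
value at the last tied rank. A probe is called differential when
q < 0.05, its modal pattern is non-null and that pattern's posterior
probability exceeds pb = 0.5; argmax ties resolve to the lowest pattern
index (male cluster major). Default run length is 30,000 sweeps with
10,000 burn-in; the validation runs below use 3,000/1,000, which the
strong-signal studies mix well within.

## Moderated linear-model stage

Per probe, OLS on the six-column tissue × sex cell-means design (errors on
an empty cell; warns on singleton cells, which are expected in the
nine-sample layout). Residual variances are shrunk toward a prior value
s0² with prior degrees of freedom d0, estimated by moment matching of
log s² (digamma/trigamma identities; trigamma inverted by Newton iteration
to 1e-8). When the observed spread of log s² does not exceed its pure
chi-square sampling floor, d0 = ∞ and s0² is the plain mean of the
variances — the convention of the Bioconductor reference implementation,
against which the whole stage is cross-checked in the test suite. The
moderated t for contrast t is b̂_jt/(s̃_j √v_jt) on d_j + d0 degrees of
freedom (normal reference when d0 = ∞); the joint moderated F over the
three male−female contrasts uses the quadratic form in the contrast
covariance divided by 3·s̃², on (3, d_j + d0). BH adjustment is applied to
the F p-values. With d0 = 0 the stage reduces exactly to classical
per-probe t/F tests.

## Survival screening

Candidate genes are screened one at a time against overall survival with
h(t) = h0(t)·exp(b1·X1), X1 the gene's continuous expression (the default;
dichotomised groups are for presentation). The Breslow partial likelihood
is maximised by Newton–Raphson (tolerance 1e-8, ≤ 50 iterations, steps
damped to ±5); ties share a risk set. A covariate constant within every
risk set yields a degenerate fit (b1 = 0, infinite SE, p = 1); a monotone
likelihood (perfect separation) is capped at |b1| = 20 and flagged
non-converged. Wald p-values are BH-adjusted across genes. The sign column
follows the screening table convention: "+" means higher expression is
associated with longer survival (b1 < 0). Kaplan–Meier curves are computed
with lifelines and exported as (time, survival, at-risk) step tables;
dichotomisation thresholds are user-supplied per gene (≤ threshold → low).

## Synthetic data

The generator runs the trajectory model forward under the study's
conditions. Defaults: 200 probes; the nine-sample layout (ATM and NTM with
two males and one female, CAM with one male and two females, so both
strata cover all tissues and some cells are singletons); pattern weights
0.25 on the null and the rest uniform over the eight discordant families;
slope magnitudes 2.0 + Uniform(0, 0.5) on the M-value scale with signs
dictated by the pattern; intercepts N(0, 1.5²); residual SD 0.3. M-value
magnitudes of ~2 correspond to beta-level differences of roughly 0.3–0.5
around mid-range — strong but realistic for tissue-level contrasts — and
the residual SD matches the reproducibility of array M-values away from
the boundaries. The survival generator draws per-gene standard-normal
expression, exponential event times with rate 0.1·exp(Σ b1_g X_g) for a
238-subject cohort, and independent uniform censoring whose upper bound is
calibrated by bisection to a 30% censoring fraction.

What the generator does **not** emulate: Illumina probe chemistry and
detection noise, beta-value boundary compression and heteroscedasticity,
batch effects, probe cross-reactivity, spatial correlation along the
genome, or correlated expression between genes. Passing recovery tests
therefore demonstrate the correctness and calibration of the inference
machinery under the model's own assumptions, not robustness to
array-specific artefacts.

## Validation summary (computed by tests and `scripts/acceptance.py`)

* Pattern recovery: five simulated studies of 200 probes at the default
  strong-signal settings, 3,000 sweeps / 1,000 burn-in — modal-pattern
  accuracy ≥ 0.9 and empirical FDR of the q < 0.05 selection ≤ 0.10.
* Null calibration: on all-flat studies of 500 probes the selected
  fraction stays ≤ 0.08 (observed: 0).
* Small-n conservatism of the moderated stage: on global-null studies of
  2,000 probes at n = 9, BH-adjusted p < 0.05 finds nothing in ≥ 90% of 20
  seeds.
* Oracle equivalences: BH against the literal step-up definition; the
  moderated pipeline at d0 = 0 against classical t; the full moderated
  stage against the Bioconductor reference; the Cox fit against a grid
  maximiser of the same partial likelihood and against lifelines;
  Kaplan–Meier against hand-computed product limits; ANOVA against
  `scipy.stats.f_oneway`.
* Cox recovery: a true log hazard ratio of 1.0 recovered within 3 SE at
  n = 500.

These problem sizes were chosen to exercise the study-shaped regime while
keeping the full validation run in the minutes range on a single CPU.

## Known limitations

* Exactly two strata and three tissue levels are supported; other designs
  are rejected with an error.
* The intercept prior centres on the stratum mean, which includes slope
  effects; with the weak variance (10) the induced bias is negligible, but
  a centred hierarchical intercept would be cleaner.
* Pattern probabilities are empirical frequencies, so their resolution is
  1/(retained draws); q-values inherit that granularity.
* The Cox stage is univariate by design — no multivariable adjustment or
  proportional-hazards diagnostics.
* The moderated stage's singleton cells contribute no residual degrees of
  freedom; with d_j = 3 the variance-prior fit frequently returns d0 = ∞,
  which is expected behaviour at this sample size, not a defect.
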
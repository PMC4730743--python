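# Methods

## Data model and normalization

The universal input is a long table of `(cell_line, replicate, dose_gy,
sf)` records. Surviving fractions must be strictly positive; every cell
line must be observed at every dose of the common grid, while replicate
counts may differ between lines. When raw colony counts are supplied,
each replicate's plating efficiency (PE) is taken from its **own**
unirradiated control and `sf = (n_colonies/n_seeded) / PE`, so the
control maps to exactly 1. Normalizing against the replicate's own
control (rather than an across-replicate mean PE) anchors every
replicate's curve at SF(0) = 1, which is also what both regression
models assume; the alternative convention would leave dose-0 residuals
in the data. Multivariate analyses consume the cell-line × dose matrix
of replicate-mean SF in percent, excluding the dose-0 column (constant
100%, zero variance, would break standardization).

## LQ regression

Per line, `ln sf` is regressed on `(D, D²)` by OLS **without
intercept**, forcing the curve through ln SF = 0 at zero dose.
Consequences handled explicitly:

* Dose-0 rows have response 0 and fitted value 0, so they never move the
  coefficients; by default they are retained and counted in the residual
  degrees of freedom (keeping N consistent with the non-linear module),
  with `include_dose0=False` available. Because those rows are exact,
  retaining them deflates σ̂ and the coefficient standard errors
  slightly at small N; calibration checks of the interval coverage are
  therefore run on the noisy rows only, where 95% CIs cover the truth at
  the nominal rate.
* R² is reported in the uncentered form 1 − RSS/Σ(ln y)², the natural
  definition for a no-intercept model (the centered form, also exposed
  as `r_squared_centered`, can be negative here).
* Coefficients are reported as estimated — negative for decaying
  survival — and α/β is their raw quotient, positive when both are
  negative. The delta-method SE of the ratio uses the full coefficient
  covariance; |β| below 1e-12 flags the ratio as unstable (infinite SE).
  Shallow, nearly-log-linear lines can legitimately return a positive β̂
  and hence a negative ratio; the estimate is not censored.

## Log-logistic family

The mean function is evaluated verbatim for D > 0 and special-cased to
f(0) = 1 (the continuity limit; no log of zero is ever taken). Parameter
bounds: φ₁ ∈ [0, 1), φ₂ > 0, φ₃ > 0, φ₄ > 0. The Weibull comparator
uses the decreasing extreme-value curve on log dose,
f = φ₁ + (1−φ₁)·exp(−exp(φ₃[ln D − ln φ₂])), a standard three-parameter
dose-response convention (φ₂ is its inflection-scale dose, not an ED50).

**Joint fitting.** Lines are fitted independently by bounded trust-
region least squares on the raw SF scale (their RSS contributions are
separable), but the reported likelihood pools the residuals under one
shared Gaussian variance: ln L = −N/2·[ln 2π + ln(RSS/N) + 1] at the ML
variance RSS/N, and AIC = 2(p_total + 1) − 2 ln L where p_total = lines ×
free parameters and the +1 is the shared variance. So a 9-line panel
reports 37/28/19/10 estimated parameters for the 4-/3-/2-/1-parameter
members. σ̂ = sqrt(RSS/(N − p_total)). Per-parameter Wald SEs and
two-sided p-values use the shared σ̂² with the per-line Jacobian
(t reference with N − p_total df).

**Self-starting.** φ₁ starts just below the smallest observed SF
(clipped to [0, 0.5]); φ₂ at the linearly interpolated dose where the
per-dose mean SF crosses 0.5 (falling back, with a flag, to the median
nonzero dose when no crossing exists); φ₃ at the slope of
logit-transformed mean SF on ln dose (clipped to [0.1, 50]); φ₄ at 1.
Convergence uses ftol 1e-10 / xtol 1e-8, at most 500·(q+1) function
evaluations, and up to 20 multiplicatively jittered restarts (lognormal,
scale 0.3; additive for φ₁, which often starts at the boundary) driven
by a user seed, default 0. Non-convergent lines are flagged but the best
solution found still enters the totals.

**Effective doses** come from the closed-form inversion of the mean
function; the requested level must lie strictly between φ₁ and 1. In
the reduced (φ₁ = 0, φ₄ = 1) member ED50 equals φ₂ exactly.

## Model selection and lack of fit

Candidates are ranked by AIC ascending (ties broken by name for
determinism). The recommendation equals the AIC winner unless the
opt-in `prefer_free_asymptote` rule is set, which promotes the best
member with a free lower asymptote: pinning φ₁ = 0 asserts that no
subpopulation survives arbitrarily high doses, a biological claim the
data cannot establish. The rule is never applied silently.

The lack-of-fit F-test compares a family fit with the saturated ANOVA
model that places one free mean on every (cell line × dose) cell on the
SF scale — the per-cell construction is required for the multi-line fit
to be nested in it. F = [(RSS_sub − RSS_full)/(df_sub − df_full)] /
(RSS_full/df_full) with the upper-tail F p-value; the test needs
replication somewhere in the panel (df_full > 0). No multiplicity
adjustment is applied anywhere.

## Clustering

Features: raw mean SF in percent (default), its natural log (log of the
mean, not mean of logs), or the single SF2 column. Distances are
Euclidean. Ward linkage defaults to the squared-distance Lance–Williams
update (heights track sqrt(2·ΔESS), so the merge order equals exhaustive
minimal-ESS-increase merging, which the tests verify by brute force);
the classical raw-distance variant is available as `ward_d`, implemented
by the exact algebraic trick of feeding sqrt-distances to the squared
form and squaring the heights. Single/complete/average linkage pass
through for sensitivity analysis. The best cut maximizes the gap between
consecutive fusion heights over k = 2..n−1 (ties to the smaller k);
silhouette widths use the standard (b−a)/max(a,b) index with s = 0 for
singletons. Tie-breaks and cluster-id assignment are deterministic in
label order. Dendrograms export as Newick with height differences as
branch lengths.

## PCA scoring

Columns of the mean-SF matrix are standardized (sample variance, n−1);
C = Xsᵀ Xs/(n−1) is eigendecomposed with eigenvalues descending and each
eigenvector oriented so its entry sum is non-negative. With all-positive
inter-dose correlations this makes every PC1 loading positive, so the
score z₁ = Xs v₁ increases with survival at every dose: high score =
radioresistant. Scores use unit-norm eigenvectors (score variance =
λ_r exactly, an invariant the tests enforce); rescaled loadings
√λ_r·v_r are the component-variable correlations. Kaiser's rule retains
eigenvalues strictly greater than 1. Score-parameter association uses
Pearson r with the two-sided t-transform p-value (n−2 df).

## Synthetic panels

`paper_like_config` emulates the motivating study design: 9 lines —
3 sensitive (midpoint dose φ₂ uniform on 1.0–1.5 Gy) and 6 resistant
(2.3–2.8 Gy) — at doses {0, 1, 2, 4, 6, 8, 10} Gy with 3 or 4
replicates per line and SF-scale noise SD 0.075, the residual scatter a
well-fitting sigmoid leaves on real panels of this kind. Slope factors
are uniform on 1.3–2.3 (sensitive) and 2.0–3.5 (resistant): all curves
steeper than the standard log-logistic, sensitive lines shallower than
resistant ones, so group curves can cross at high doses as real panels
do. Asymptotes are zero. LQ truths add noise on the log scale instead.
Additive SF-scale draws are resampled until positive — a slight
truncation of the Gaussian error model that matters only where the mean
SF is within ~2σ of zero (the highest doses). Dose-0 records are pinned
to SF = 1 exactly, matching the normalization convention. One
`numpy.random.default_rng` stream per panel makes every dataset
bit-reproducible from its integer seed; count mode draws
n_colonies ~ Poisson(n_seeded · PE · mean SF).

**What the generator does and does not emulate.** It reproduces the
design (grid, replicate structure, group separation, noise scale) but
draws lines from two tight parameter clusters rather than the continuous
spread of resistance real panels show. One visible consequence: on real
panels of this kind the first principal component can carry ~77% of the
variance and is the only Kaiser-retained component, whereas on these
synthetic panels PC1 carries ~40–60% and 2–3 components pass Kaiser —
the high- and low-dose columns of the mean-SF matrix are partly noise
when within-group spread is small. Tests therefore check the PCA
*invariants* and group ordering on synthetic panels, and check the
variance-proportion figures on the published worked-example correlation
matrix. Replicate-level random effects, overdispersed counts and
fractionated schedules are out of scope.

## Problem sizes

Simulation-based checks use the study-design panel (9 lines × 7 doses ×
3–4 replicates): 500 runs for ED50 recovery (median absolute error
< 0.25 Gy), 200 panels for the LQ-vs-log-logistic σ̂ direction and for
two-group cluster recovery, 1000 runs for lack-of-fit type-I calibration
(interior asymptote truth, noise 0.05, so the positivity truncation and
the φ₁ ≥ 0 boundary do not distort the F reference), 2000 fits for LQ
CI coverage. The whole suite runs in a few minutes on one CPU.
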
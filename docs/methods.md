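# Methods

This note documents the models implemented in `socchrono`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish about real field data.

## Stock accounting

The SOC stock of a depth interval is (%C/100) · BD · D · 10⁴ with BD in
g cm⁻³ (numerically equal to Mg m⁻³) and D in m; the 10⁴ m² ha⁻¹ factor makes
the result Mg C ha⁻¹. Profile totals are sums over the canonical interval set
{0–0.15, 0.15–0.3, 0.3–0.6, 0.6–0.9, 0.9–1.2} m. No gravel or carbonate
correction is applied: the accounting targets stone-poor, acid upland soils;
for soils where either matters the inputs must be pre-corrected.

**Equal-BD correction.** Stocks of converted plots are computed from the
plot's own carbon concentration and the *same-cluster reference plot's* BD
profile, never a study-wide mean — the correction is a within-pair,
per-interval substitution so that equal soil masses are compared. The
uncorrected variant (`bd_correction: false`) exists only to quantify the
error this removes; both variants appear side by side in
`bd_correction_comparison.csv`.

**Paired changes.** Within each cluster, converted plots are averaged per
interval *before* differencing against the forest (mean-then-difference), and
relative changes are 100 · Δ / forest stock. Cluster is the replication unit:
summaries report mean ± SE with n = clusters. A plot-level pairing of the
relative differences (one value per converted plot) is kept as a separate
accessor for the covariate screen, where the observational unit is the
plantation; the pairing level of the screen is an explicit option
(`pairing_level: plot|cluster`) rather than a hidden default.

**Litter and stand structure.** Litter carbon stock is the per-frame carbon
mass scaled to a hectare, averaged over the frames of a plot (default frame
0.04 m², 10 frames). Basal area is π(dbh/200)² per stem; bamboo clumps
contribute the measured stem's basal area times the clump's stem count, and
are included in total but not tree basal area. Forest inventories drop trees
at or below the 4-cm DBH threshold at validation.

## Land-use inference

A linear mixed model with fixed effects land use + depth + land use × depth
and a random intercept per cluster, estimated by REML (statsmodels `MixedLM`).
REML is the conventional default for variance components; the fixed-effect
covariance is computed as the model-based GLS covariance at the estimated
variance components, which stays well defined when the cluster variance is
estimated on the boundary. Rubber-minus-forest contrasts per depth are Wald
tests on that covariance; the Holm family is the set of per-depth contrasts
for one response (five tests). The assumptions are the usual ones: cluster
effects and residuals Gaussian, plots exchangeable within cluster given land
use, no spatial correlation beyond the cluster intercept.

**Variance function.** When residual spread visibly differs between strata,
per-stratum residual variances (by land use or by depth) can be requested.
statsmodels has no unequal-variance residual structure for `MixedLM`, so this
variant is fitted by a small REML routine in `landuse.py`: β profiled out by
GLS, the log-variances optimised by Nelder–Mead. The trigger is manual
(config), mirroring a residual-inspection workflow; no automated
heteroscedasticity test is run. On homoscedastic data the two routes agree
(tested).

**Spearman screen.** Mid-ranks for ties; rho is Pearson correlation of the
ranks (tested as an identity). P-values use the exact permutation
distribution for n ≤ 9 (the full n! enumeration, cached per n) and the
t-approximation above; the cut at 9 keeps the enumeration under half a
million permutations. Marginal significance (p ≤ 0.1) is flagged with a
dagger. Constant columns report a missing rho rather than 0.

## Chronosequence decay models

Each plantation contributes one point per depth interval: t = years since
conversion, y = 100 · converted / forest stock (BD-corrected). Points are
pooled across clusters; fits are per depth interval, independently, by
default for the upper three intervals where decline is detectable.

Both pool models fix X₀ = 100 %: the response is by construction 100 % of the
paired forest at t = 0, so freeing X₀ would spend a degree of freedom on a
quantity known by definition (an option exists to free it, off by default).

Numerical choices:

* **Optimiser**: `scipy.optimize.curve_fit` (trust-region reflective, since
  bounds are set) with xtol = ftol = gtol = 1e-10.
* **Bounds**: Xe ∈ (0, 120], k, k₁, k₂ ∈ (0, 5] yr⁻¹, X₁ ∈ [0, 100] —
  physical plausibility with headroom for noisy proportions slightly above
  100 %.
* **Start values**: mono Xe = min(y), k = 0.1 yr⁻¹; bi X₁ = 30 %, k₁ = 0.3,
  k₂ = 0.01 yr⁻¹; chosen for basin coverage.
* **Multi-start**: 5 jittered restarts (seeded, factors in [0.5, 1.8]); the
  lowest-SSE solution wins. Non-convergence returns `converged=False` rather
  than raising.
* **Uncertainty**: asymptotic SEs from the Jacobian; intervals and parameter
  Wald tests use t quantiles on n − p degrees of freedom (the `nls`
  reporting convention), which matters at n = 11.
* **Goodness of fit**: Pearson r between observed and fitted values with its
  p-value.

**Steady state.** Declared at the first t where X(t) − Xe ≤ 0.01·Xe, i.e.
within 1 % *of the equilibrium value*; closed form
t\* = ln((100 − Xe)/(0.01·Xe))/k. The alternative reading — 1 % of the
decaying amplitude (X₀ − Xe) — is defensible but is not the default; only the
Xe-relative rule is implemented. No steady state is reported when k ≤ 0 or
Xe ≥ 100.

**Model choice.** Parsimony-first: the one-pool model is selected when any
two-pool rate is non-significant at 0.05 **or** the two fitted curves never
differ by more than 0.5 percentage points (configurable) over the observed
ages; otherwise the two-pool model wins. With ~11 points and ages ≥ 5 yr the
labile pool is rarely identifiable, and the tie-break makes that an explicit,
logged decision instead of an overfit.

## Synthetic-study generator

The generator emulates the reference design: 7 clusters, one forest plot
each, (2,2,2,1,1,2,1) rubber plots per cluster (11 total), ages drawn without
replacement from {5, 8, 10, 13, 16, 20, 24, 28, 33, 39, 46} yr, five depth
intervals, 400-m² plots.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| forest baseline stocks | 43.9 / 38.9 / 52 / 35.2 / 26 Mg C ha⁻¹ | reference-study profile magnitudes |
| between-cluster SD | 10 % of the baseline (lognormal) | within-cluster pairing is the design's point; the true magnitude is unpublished, so this is an exposed free choice |
| decay truth (Xe, k) | Xe = 68/75/85/90/95 %, k = 0.2 yr⁻¹ | topsoil equilibrium near two-thirds of baseline, steady state near 20 yr; deep subsoil losses small and hard to detect |
| stock noise | 5 % multiplicative (lognormal) | keeps stocks positive and SEs proportional to means; ~4–5 percentage points on the proportion scale |
| bulk density | forest 1.0/1.2/1.3/1.3/1.3 g cm⁻³, cluster SD 0.05 | field magnitudes; rubber BD = forest BD + configurable shift (default 0) |
| litter | ~25 g/frame, 41 % C, C:N 45, land-use neutral | litter stocks of ~2–3 Mg C ha⁻¹ with no land-use signal |
| rubber stand | 18–22 stems/plot, DBH = 6.5 + 0.55·age cm (CV 8 %) | basal areas 3–42 m² ha⁻¹ growing tightly with age |

Carbon concentrations are back-computed by inverting the stock equation *at
the forest BD*, so the generated truth stocks are the equal-soil-mass stocks
and the corrected pipeline reproduces them exactly (a tested round-trip
identity). Setting `bd_rubber_shift > 0` creates the compaction scenario in
which the uncorrected analysis understates losses. Forest plots carry no
measurement noise on stocks: their baseline *is* the cluster's reference
quantity, so all proportion noise comes from the converted plots.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: within-plot sampling error of the composite (one row
per plot × interval), spatial autocorrelation between clusters, erosion or
carbon-input dynamics (the decay curve is imposed, not mechanistic),
correlated chemistry (pH/ECEC are static draws), and texture–carbon coupling.
Parameter-recovery results therefore validate the estimators under the
design's assumptions, not the assumptions themselves.

## Problem sizes

The test suite and the acceptance script run at the study's own scale: 18
plots, 90 horizon rows, 11 chronosequence points per interval. The
parameter-recovery check uses 200 independent replicates of the full design
(~12 s); the steady-state closed form is verified against a 0.001-yr grid
scan over 1000 random parameter draws; Holm and Spearman implementations are
verified against brute-force oracles on random inputs.

## Known limitations

* Depth intervals must match the canonical set; irregular profiles are
  rejected rather than re-binned.
* The mixed model offers only the treatment-coded land use × depth structure;
  no model selection over fixed effects.
* The two-pool fit frequently sits on the X₁ boundary at small n — its SEs
  are then untrustworthy, which is exactly why model selection defaults to
  parsimony.
* The exact Spearman permutation p-value treats ties by conditioning on the
  observed mid-rank pattern of one margin.
* No spatial coordinates, pedotransfer functions, or process-based carbon
  models.
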
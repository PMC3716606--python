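# socchrono

Soil organic carbon (SOC) stock accounting and chronosequence decay analysis
for clustered, paired land-use change studies.

## The problem

When a forest is converted to a plantation, the soil slowly loses (or gains)
organic carbon. Measuring that change is harder than it sounds, for two
reasons this package addresses head-on:

1. **Bulk density is a confounder.** Land-use change compacts or loosens the
   soil, so comparing stocks computed with each plot's own bulk density (BD)
   mixes a real carbon change with a change in how much soil sits in a fixed
   depth slice. `socchrono` computes the converted plot's stocks with the
   *reference* plot's BD (an equal-soil-mass comparison) and can quantify the
   error the correction removes.
2. **Time series do not exist.** Nobody resampled the same plot for 46 years.
   Under *space-for-time substitution*, plantations of different ages within
   a matched cluster stand in for one site through time, and the decline is
   modelled as exponential decay toward a new equilibrium.

The package is aimed at ecosystem biogeochemists running (or re-analysing)
paired-plot designs: spatial clusters each holding one reference forest plot
and one to three converted plots of known age, sampled over five depth
intervals down to 1.2 m.

## The models

The SOC stock of a depth interval of thickness *D* (m) is

> stock [Mg C ha⁻¹] = (%C / 100) · BD [g cm⁻³] · D · 10⁴

Paired changes are computed per cluster (converted plots averaged first, then
differenced against the forest, relative changes as % of the forest stock).
Land-use inference uses a linear mixed model — fixed effects land use × depth,
a random intercept per cluster — with per-depth Wald contrasts adjusted by
Holm's step-down correction, plus a Spearman rank screen of carbon against
site covariates.

The chronosequence expresses each plantation's stock as a percentage
*y = 100 · rubber / forest* and fits, by nonlinear least squares with
*X₀ = 100 %* fixed:

* **one-pool model**: X(t) = Xe + (100 − Xe)·e^(−kt), with equilibrium Xe (%)
  and decay rate k (yr⁻¹);
* **two-pool model**: X(t) = X₁·e^(−k₁t) + (100 − X₁)·e^(−k₂t) (labile +
  stable pools).

Goodness of fit is the Pearson correlation *r* between observed and fitted
values; the two-pool model is preferred only when its rates are significant
and its curve actually departs from the one-pool curve. The steady state is
the first time X(t) comes within 1 % of Xe, which has the closed form
t\* = ln((100 − Xe)/(0.01·Xe))/k.

A synthetic-study generator with the same causal structure (cluster baselines,
depth-specific decay truth, measurement noise, age-driven stand growth)
makes every stage testable and supports parameter-recovery simulation.

## Worked example

```python
import socchrono as sc

bundle, truth = sc.generate_study(seed=42)          # 7 clusters, 11 plantations
profiles = sc.bundle_stock_profiles(bundle)          # BD-corrected stocks
changes = sc.bundle_cluster_changes(bundle, profiles)
print(sc.summarize_changes(changes).round(2).to_string(index=False))

top = sc.CANONICAL_INTERVALS[0]                      # 0-0.15 m
pts = sc.proportions(bundle, profiles, top)
fit = sc.SoilCarbonDecayModel.from_points(pts, kind="mono").fit(seed=42)
print(fit.summary())
```

prints

```
interval  abs_mean  abs_se  rel_mean  rel_se  n
  0-0.15    -13.00    0.41    -31.77    0.96  7
0.15-0.3     -9.75    0.44    -25.02    1.08  7
 0.3-0.6     -7.36    0.77    -14.37    1.58  7
 0.6-0.9     -3.53    0.54    -10.13    1.53  7
 0.9-1.2     -1.21    0.42     -5.00    1.78  7
   total    -34.85    1.26    -18.11    0.64  7

Decay model: mono-exponential (X0 fixed at 100 %)
n = 11, converged = True, SSR = 37.98
Pearson r(obs, fitted) = 0.9014 (p = 0.00015)

 param   estimate         SE        t     P>|t|
    Xe    65.6593     0.8387   78.291  4.58e-14
     k     0.2084     0.0265    7.861  2.54e-05

steady state: t* = 18.98 yr (X(t*) = 66.32 %)
```

Reading it: this synthetic landscape lost on average 34.9 ± 1.3 Mg C ha⁻¹
(18.1 % of the forest stock) over the whole 1.2-m profile, concentrated in
the topsoil; the 0–0.15 m layer decays to an equilibrium of ~66 % of the
forest stock at a rate of ~0.21 yr⁻¹, reaching steady state after ~19 years.

## Command line

```sh
socchrono synth --seed 3 --out study/        # four input CSVs + truth.json
socchrono run  --input-dir study/ --out out/ # the full analysis
socchrono recover --reps 200 --seed 1        # parameter-recovery simulation
```

`socchrono run` emits six report tables (soil characteristics, litter and
stand summaries, stock changes with mixed-model significance, the covariate
correlation screen, decay fits plus curve tables, and the corrected-vs-
uncorrected BD comparison) together with a `manifest.json` recording seeds,
input digests and every decision the run took.

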
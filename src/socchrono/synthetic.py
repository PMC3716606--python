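"""Synthetic clustered paired-plot studies with known ground truth.

The generator emulates the design of a space-for-time soil carbon study in a
tropical forest-to-plantation landscape: spatial clusters each holding one
secondary-forest reference plot and one to three rubber plots of known age,
five depth intervals to 1.2 m, composite horizon samples, litter frames and a
stem inventory. Defaults reproduce the reference design shape — 7 clusters,
11 plantations, ages spread over 5-46 yr — and field-realistic magnitudes:
forest profile stocks of roughly 44/39/52/35/26 Mg C ha^-1 down the profile,
bulk densities near 1.0-1.3 g cm^-3, litter at ~41 % C, and stand basal areas
growing with plantation age.

The causal structure is what the analysis assumes:

* each cluster draws a forest baseline stock per interval (lognormal
  between-cluster variation around the configured means);
* a rubber plot of age t holds ``baseline * mono_exp(t; Xe, k) / 100`` of the
  baseline, times multiplicative lognormal measurement noise — the depth
  -specific (Xe, k) truth is what the chronosequence module should recover;
* carbon concentrations are back-computed from the stock equation using the
  cluster's *forest* bulk density, so the generated stocks are the
  equal-soil-mass (BD-corrected) stocks; the plantation's own measured BD can
  be shifted upward (compaction) to exercise the corrected-vs-uncorrected
  divergence;
* litter is land-use neutral; rubber basal area is a tight function of age.

Every generating parameter is stored in a :class:`TruthRecord` so that
pipeline output can be scored against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronosequence import DecayResults, mono_exp
from .schemas import (
    CANONICAL_INTERVALS,
    ConfigurationError,
    StudyBundle,
    assemble_study,
)
from .stocks import StockProfile

__all__ = ["SyntheticStudyConfig", "TruthRecord", "generate_study", "truth_report"]

_N_IV = len(CANONICAL_INTERVALS)


@dataclass
class SyntheticStudyConfig:
    """All generator knobs. Defaults are the reference study conditions."""

    n_clusters: int = 7
    #: rubber plots per cluster (1-3 each); default totals 11 plantations.
    rubber_per_cluster: tuple = (2, 2, 2, 1, 1, 2, 1)
    #: plantation ages drawn without replacement (years since conversion).
    ages: tuple = (5, 8, 10, 13, 16, 20, 24, 28, 33, 39, 46)
    age_range: tuple = (1.0, 60.0)

    #: forest baseline stock means per interval, Mg C ha^-1 (profile to 1.2 m).
    forest_stock_mean: tuple = (43.9, 38.9, 52.0, 35.2, 26.0)
    #: between-cluster SD of baselines as a fraction of the mean (lognormal).
    cluster_sd_frac: float = 0.10
    #: depth-specific decay truth: equilibrium proportion (%) and rate (1/yr).
    xe_pct: tuple = (68.0, 75.0, 85.0, 90.0, 95.0)
    k_per_yr: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: multiplicative measurement noise on rubber stocks, % of the stock.
    stock_noise_sd_pct: float = 5.0

    #: forest bulk density means per interval (g cm^-3) and between-cluster SD.
    bd_forest_mean: tuple = (1.0, 1.2, 1.3, 1.3, 1.3)
    bd_cluster_sd: float = 0.05
    #: systematic rubber-minus-forest BD shift (compaction stress test).
    bd_rubber_shift: float = 0.0
    bd_rubber_noise_sd: float = 0.0

    #: texture: silt+clay % base, variance components, and gradients.
    silt_clay_base: float = 68.0
    silt_clay_depth_offset: tuple = (-2.0, 0.0, 3.0, 3.0, 3.0)
    silt_clay_cluster_sd: float = 5.0
    silt_clay_plot_sd: float = 2.0
    #: optional land-use texture shift (0 keeps land uses exchangeable).
    texture_landuse_shift: float = 0.0
    #: silt+clay percentage points per metre of altitude above the mid-range.
    altitude_texture_slope: float = 0.05

    altitude_range: tuple = (700.0, 830.0)
    slope_range_pct: tuple = (10.0, 60.0)
    plot_area_m2: float = 400.0

    #: chemistry (static draws; first two intervals are "topsoil" C:N).
    cn_topsoil: float = 12.2
    cn_subsoil: float = 9.5
    cn_sd: float = 0.8
    ph_h2o_mean: tuple = (4.7, 4.9, 5.0, 5.0, 4.9)
    ph_kcl_mean: tuple = (3.9, 3.9, 4.0, 4.0, 4.0)
    ph_sd: float = 0.12
    ecec_mean: tuple = (50.0, 33.0)  # 0-0.15 m and 0.6-0.9 m
    ecec_sd: float = 8.0
    base_sat_mean: tuple = (24.0, 11.0)
    base_sat_sd: float = 5.0

    #: litter (land-use neutral): dry mass per 0.04 m^2 frame and C content.
    n_litter_samples: int = 10
    frame_area_m2: float = 0.04
    litter_mass_mean_g: float = 25.0
    litter_mass_sd_g: float = 8.0
    litter_c_pct_mean: float = 41.0
    litter_c_pct_sd: float = 2.0
    litter_cn_mean: float = 45.0
    litter_cn_sd: float = 8.0

    #: stand structure: rubber DBH grows linearly with age; forest holds a
    #: lognormal DBH mix plus bamboo clumps.
    rubber_stems: tuple = (18, 22)  # inclusive range per plot
    rubber_dbh_intercept_cm: float = 6.5
    rubber_dbh_slope_cm_yr: float = 0.55
    rubber_dbh_cv: float = 0.08
    forest_trees_mean: float = 35.0
    forest_dbh_median_cm: float = 11.0
    forest_dbh_sigma: float = 0.45
    forest_bamboo_clumps_mean: float = 5.0
    bamboo_stem_dbh_cm: float = 5.2
    bamboo_stems_range: tuple = (12, 24)

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if len(self.rubber_per_cluster) != self.n_clusters:
            raise ConfigurationError(
                "rubber_per_cluster must list one count per cluster"
            )
        if any(not (1 <= r <= 3) for r in self.rubber_per_cluster):
            raise ConfigurationError("rubber plots per cluster must be 1-3")
        if sum(self.rubber_per_cluster) > len(self.ages):
            raise ConfigurationError("not enough ages for the rubber plots")
        for name in ("forest_stock_mean", "xe_pct", "k_per_yr", "bd_forest_mean",
                     "silt_clay_depth_offset", "ph_h2o_mean", "ph_kcl_mean"):
            if len(getattr(self, name)) != _N_IV:
                raise ConfigurationError(f"{name} must have {_N_IV} entries")
        if any(not (0 < xe <= 100) for xe in self.xe_pct):
            raise ConfigurationError("xe_pct entries must lie in (0, 100]")
        for name in ("cluster_sd_frac", "stock_noise_sd_pct", "bd_cluster_sd",
                     "bd_rubber_noise_sd", "silt_clay_cluster_sd",
                     "silt_clay_plot_sd", "litter_mass_sd_g", "litter_c_pct_sd",
                     "cn_sd", "ph_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthRecord:
    """Everything needed to score pipeline output against the generator."""

    seed: int
    config: dict
    plot_ids: list
    #: cluster -> interval label -> forest baseline stock (Mg C ha^-1)
    baselines: dict
    #: rubber plot -> interval label -> generated (BD-corrected) stock
    rubber_stocks: dict
    #: rubber plot -> age (years)
    ages: dict
    #: interval label -> (Xe %, k 1/yr)
    decay: dict

    def expected_cluster_losses(self) -> pd.DataFrame:
        """Per-cluster, per-interval generated losses (rubber mean - forest)."""
        rows = []
        # rubber plots map to clusters via the id convention C<k>R<j>
        for cluster, base in self.baselines.items():
            members = [p for p in self.rubber_stocks if p.startswith(f"{cluster}R")]
            for iv_label, b in base.items():
                rubber_mean = float(
                    np.mean([self.rubber_stocks[p][iv_label] for p in members])
                )
                rows.append(
                    {"cluster_id": cluster, "interval": iv_label,
                     "abs_true": rubber_mean - b,
                     "rel_true": 100.0 * (rubber_mean - b) / b}
                )
        return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_study(
    config: SyntheticStudyConfig | None = None, seed: int = 0
) -> tuple[StudyBundle, TruthRecord]:
    """Generate one synthetic study; same (config, seed) -> identical bundle."""
    cfg = config or SyntheticStudyConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    ivs = CANONICAL_INTERVALS
    sigma = cfg.stock_noise_sd_pct / 100.0

    total_rubber = sum(cfg.rubber_per_cluster)
    ages = np.array(cfg.ages, dtype=float)
    age_assign = rng.permutation(ages)[:total_rubber]

    plots_rows, horizon_rows, litter_rows, tree_rows = [], [], [], []
    baselines: dict = {}
    rubber_stocks: dict = {}
    age_map: dict = {}
    age_iter = iter(age_assign)

    mid_alt = float(np.mean(cfg.altitude_range))

    def _texture(cluster_dev, altitude, land_use, rng):
        sc = (
            cfg.silt_clay_base
            + np.asarray(cfg.silt_clay_depth_offset)
            + cluster_dev
            + rng.normal(0, cfg.silt_clay_plot_sd, _N_IV)
            + cfg.altitude_texture_slope * (altitude - mid_alt)
            + (cfg.texture_landuse_shift if land_use == "rubber" else 0.0)
        )
        return np.clip(sc, 20.0, 95.0)

    def _chemistry(rng):
        cn = np.r_[
            rng.normal(cfg.cn_topsoil, cfg.cn_sd, 2),
            rng.normal(cfg.cn_subsoil, cfg.cn_sd, 3),
        ]
        ph_w = rng.normal(cfg.ph_h2o_mean, cfg.ph_sd)
        ph_k = rng.normal(cfg.ph_kcl_mean, cfg.ph_sd)
        ecec = np.full(_N_IV, np.nan)
        bsat = np.full(_N_IV, np.nan)
        for pos, j in ((0, 0), (1, 3)):  # 0-0.15 m and 0.6-0.9 m only
            ecec[j] = max(rng.normal(cfg.ecec_mean[pos], cfg.ecec_sd), 1.0)
            bsat[j] = float(np.clip(rng.normal(cfg.base_sat_mean[pos], cfg.base_sat_sd), 0.5, 100))
        return cn, ph_w, ph_k, ecec, bsat

    def _add_horizons(plot_id, stocks, bd, texture, rng):
        cn, ph_w, ph_k, ecec, bsat = _chemistry(rng)
        for j, iv in enumerate(ivs):
            c_pct = stocks[j] / (bd[j] * iv.thickness_m * 100.0)
            horizon_rows.append(
                {
                    "plot_id": plot_id,
                    "top_m": iv.top_m,
                    "bottom_m": iv.bottom_m,
                    "c_pct": c_pct,
                    "n_pct": c_pct / cn[j],
                    "bd_g_cm3": bd[j],
                    "sand_pct": 100.0 - texture[j],
                    "silt_clay_pct": texture[j],
                    "ph_h2o": ph_w[j],
                    "ph_kcl": ph_k[j],
                    "ecec_mmolc_kg": ecec[j],
                    "base_sat_pct": bsat[j],
                }
            )

    def _add_litter(plot_id, rng):
        c_pct = float(rng.normal(cfg.litter_c_pct_mean, cfg.litter_c_pct_sd))
        cn = max(float(rng.normal(cfg.litter_cn_mean, cfg.litter_cn_sd)), 5.0)
        mass = np.maximum(
            rng.normal(cfg.litter_mass_mean_g, cfg.litter_mass_sd_g, cfg.n_litter_samples),
            0.5,
        )
        for s, m in enumerate(mass, start=1):
            litter_rows.append(
                {"plot_id": plot_id, "sample_id": s, "mass_g": float(m),
                 "frame_area_m2": cfg.frame_area_m2, "c_pct": c_pct,
                 "n_pct": c_pct / cn}
            )

    def _add_rubber_trees(plot_id, age, rng):
        n = int(rng.integers(cfg.rubber_stems[0], cfg.rubber_stems[1] + 1))
        mean_dbh = cfg.rubber_dbh_intercept_cm + cfg.rubber_dbh_slope_cm_yr * age
        dbh = mean_dbh * np.exp(rng.normal(0, cfg.rubber_dbh_cv, n))
        for d in dbh:
            tree_rows.append(
                {"plot_id": plot_id, "stem_kind": "tree", "dbh_cm": float(d),
                 "stems_in_clump": 1}
            )

    def _add_forest_trees(plot_id, rng):
        n = max(int(rng.poisson(cfg.forest_trees_mean)), 5)
        dbh = np.exp(rng.normal(np.log(cfg.forest_dbh_median_cm), cfg.forest_dbh_sigma, n))
        dbh = np.maximum(dbh, 4.05)  # inventory threshold
        for d in dbh:
            tree_rows.append(
                {"plot_id": plot_id, "stem_kind": "tree", "dbh_cm": float(d),
                 "stems_in_clump": 1}
            )
        n_clump = max(int(rng.poisson(cfg.forest_bamboo_clumps_mean)), 1)
        for _ in range(n_clump):
            tree_rows.append(
                {
                    "plot_id": plot_id,
                    "stem_kind": "bamboo_clump",
                    "dbh_cm": float(max(rng.normal(cfg.bamboo_stem_dbh_cm, 0.5), 1.0)),
                    "stems_in_clump": int(
                        rng.integers(cfg.bamboo_stems_range[0], cfg.bamboo_stems_range[1] + 1)
                    ),
                }
            )

    for c in range(cfg.n_clusters):
        cluster_id = f"C{c + 1}"
        altitude = float(rng.uniform(*cfg.altitude_range))
        baseline = np.asarray(cfg.forest_stock_mean) * np.exp(
            rng.normal(0, cfg.cluster_sd_frac, _N_IV)
        )
        bd_forest = _truncated_normal(
            rng, np.asarray(cfg.bd_forest_mean), cfg.bd_cluster_sd, 0.5, 2.0
        )
        sc_cluster_dev = float(rng.normal(0, cfg.silt_clay_cluster_sd))
        baselines[cluster_id] = {iv.label: float(b) for iv, b in zip(ivs, baseline)}

        forest_id = f"{cluster_id}F"
        plots_rows.append(
            {"plot_id": forest_id, "cluster_id": cluster_id, "land_use": "forest",
             "age_years": np.nan,
             "altitude_m": altitude + float(rng.normal(0, 5)),
             "slope_pct": float(rng.uniform(*cfg.slope_range_pct)),
             "plot_area_m2": cfg.plot_area_m2}
        )
        _add_horizons(forest_id, baseline, bd_forest,
                      _texture(sc_cluster_dev, altitude, "forest", rng), rng)
        _add_litter(forest_id, rng)
        _add_forest_trees(forest_id, rng)

        for j in range(cfg.rubber_per_cluster[c]):
            plot_id = f"{cluster_id}R{j + 1}"
            age = float(next(age_iter))
            age_map[plot_id] = age
            remaining = mono_exp(age, np.asarray(cfg.xe_pct), np.asarray(cfg.k_per_yr)) / 100.0
            noise = np.exp(rng.normal(0, sigma, _N_IV)) if sigma > 0 else np.ones(_N_IV)
            stocks = baseline * remaining * noise
            bd_rubber = bd_forest + cfg.bd_rubber_shift
            if cfg.bd_rubber_noise_sd > 0:
                bd_rubber = bd_rubber + rng.normal(0, cfg.bd_rubber_noise_sd, _N_IV)
            bd_rubber = np.clip(bd_rubber, 0.5, 2.0)
            rubber_stocks[plot_id] = {
                iv.label: float(s) for iv, s in zip(ivs, stocks)
            }
            plots_rows.append(
                {"plot_id": plot_id, "cluster_id": cluster_id, "land_use": "rubber",
                 "age_years": age,
                 "altitude_m": altitude + float(rng.normal(0, 5)),
                 "slope_pct": float(rng.uniform(*cfg.slope_range_pct)),
                 "plot_area_m2": cfg.plot_area_m2}
            )
            # C % is back-computed at the *forest* BD: the generated stocks are
            # the equal-soil-mass stocks the corrected pipeline reconstructs.
            # The plantation's own (possibly compacted) BD is what a field crew
            # would have measured in its pit.
            cn, ph_w, ph_k, ecec, bsat = _chemistry(rng)
            texture = _texture(sc_cluster_dev, altitude, "rubber", rng)
            for k_iv, iv in enumerate(ivs):
                c_pct = stocks[k_iv] / (bd_forest[k_iv] * iv.thickness_m * 100.0)
                horizon_rows.append(
                    {"plot_id": plot_id, "top_m": iv.top_m, "bottom_m": iv.bottom_m,
                     "c_pct": c_pct, "n_pct": c_pct / cn[k_iv],
                     "bd_g_cm3": float(bd_rubber[k_iv]),
                     "sand_pct": 100.0 - texture[k_iv],
                     "silt_clay_pct": texture[k_iv],
                     "ph_h2o": ph_w[k_iv], "ph_kcl": ph_k[k_iv],
                     "ecec_mmolc_kg": ecec[k_iv], "base_sat_pct": bsat[k_iv]}
                )
            _add_litter(plot_id, rng)
            _add_rubber_trees(plot_id, age, rng)

    bundle = assemble_study(
        pd.DataFrame(plots_rows),
        pd.DataFrame(horizon_rows),
        pd.DataFrame(litter_rows),
        pd.DataFrame(tree_rows),
        age_range=cfg.age_range,
    )
    truth = TruthRecord(
        seed=seed,
        config=cfg.to_dict(),
        plot_ids=bundle.plots["plot_id"].tolist(),
        baselines=baselines,
        rubber_stocks=rubber_stocks,
        ages=age_map,
        decay={iv.label: (float(xe), float(k))
               for iv, xe, k in zip(ivs, cfg.xe_pct, cfg.k_per_yr)},
    )
    return bundle, truth


def truth_report(
    truth: TruthRecord,
    *,
    profiles: dict[object, StockProfile] | None = None,
    decay_fits: dict[str, DecayResults] | None = None,
    changes_summary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score pipeline outputs against the generating truth.

    Returns one row per scored parameter with the truth, the estimate, bias,
    absolute error, and (where the output carries an SE) whether the 95 %
    interval covers the truth. Outputs must come from the bundle that produced
    ``truth``; a plot-id mismatch raises.
    """
    rows = []
    if profiles is not None:
        if set(profiles) != set(truth.plot_ids):
            raise ValueError("profiles do not match the truth record's plot ids")
        for plot_id, by_iv in truth.rubber_stocks.items():
            prof = profiles[plot_id]
            for iv in prof.intervals:
                rows.append(
                    {"parameter": f"stock[{plot_id},{iv.label}]",
                     "truth": by_iv[iv.label], "estimate": prof[iv],
                     "bias": prof[iv] - by_iv[iv.label],
                     "abs_error": abs(prof[iv] - by_iv[iv.label]),
                     "ci_covers": np.nan}
                )
    if decay_fits is not None:
        from scipy import stats as _stats

        for iv_label, fit in decay_fits.items():
            if iv_label not in truth.decay:
                raise ValueError(f"no decay truth for interval {iv_label!r}")
            xe_true, k_true = truth.decay[iv_label]
            q = _stats.t.ppf(0.975, fit.df_resid)
            for name, tru in (("Xe", xe_true), ("k", k_true)):
                est, se = float(fit.params[name]), float(fit.bse[name])
                rows.append(
                    {"parameter": f"{name}[{iv_label}]", "truth": tru,
                     "estimate": est, "bias": est - tru,
                     "abs_error": abs(est - tru),
                     "ci_covers": float(abs(est - tru) <= q * se)}
                )
    if changes_summary is not None:
        true_losses = truth.expected_cluster_losses()
        mean_true = true_losses.groupby("interval")["abs_true"].mean()
        for _, row in changes_summary.iterrows():
            if row["interval"] == "total":
                tru = float(true_losses.groupby("cluster_id")["abs_true"].sum().mean())
            else:
                tru = float(mean_true[row["interval"]])
            est, se = float(row["abs_mean"]), float(row["abs_se"])
            rows.append(
                {"parameter": f"mean_loss[{row['interval']}]", "truth": tru,
                 "estimate": est, "bias": est - tru, "abs_error": abs(est - tru),
                 "ci_covers": float(abs(est - tru) <= 1.96 * se) if se == se else np.nan}
            )
    return pd.DataFrame(rows)
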
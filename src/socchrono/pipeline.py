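"""End-to-end orchestration: read -> stocks -> changes -> inference -> decay.

``run_pipeline`` drives the full analysis over a validated study bundle (read
from CSVs, or generated synthetically when no input directory is given) and
emits six report tables plus a manifest:

* ``summary_characteristics.csv`` — per land-use means +/- SE of the soil
  characteristics by depth interval;
* ``litter_trees.csv`` — litter stock/C/C:N and basal areas per land use;
* ``stocks_changes.csv`` — per-depth and total stocks and the paired
  absolute/relative changes with mixed-model significance;
* ``correlations.csv`` — the Spearman screen of C % and relative stock
  differences against site covariates;
* ``decay_fits.csv`` (+ ``decay_curves.csv``) — chronosequence model
  parameters, goodness of fit, steady-state times and the selected model;
* ``bd_correction_comparison.csv`` — corrected vs. uncorrected change
  estimates, quantifying the error the equal-BD correction removes.

Every stage is a pure function of the validated inputs, the run configuration
and the seed; rerunning with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chronosequence import (
    SoilCarbonDecayModel,
    proportions,
    select_model,
)
from .landuse import (
    LandUseMixedModel,
    significance_stars,
    spearman_screen,
)
from .schemas import (
    CANONICAL_INTERVALS,
    FITTED_INTERVALS,
    RunConfig,
    StudyBundle,
    read_study,
)
from .stocks import (
    basal_areas,
    bundle_cluster_changes,
    bundle_stock_profiles,
    litter_stock,
    plotwise_relative_differences,
    summarize_changes,
)
from .synthetic import SyntheticStudyConfig, generate_study

__all__ = ["RunManifest", "run_pipeline", "analyze_bundle"]

CHARACTERISTIC_COLUMNS = {
    "sand_pct": "Sand (%)",
    "silt_clay_pct": "Silt and clay (%)",
    "bd_g_cm3": "Bulk density (g cm-3)",
    "cn_ratio": "C:N ratio",
    "ph_h2o": "pH (H2O)",
    "ph_kcl": "pH (KCl)",
    "ecec_mmolc_kg": "ECEC (mmolc kg-1)",
    "base_sat_pct": "Base saturation (%)",
}

COVARIATE_NAMES = [
    "litter_c_stock",
    "litter_cn",
    "total_basal_area",
    "silt_clay_pct",
    "age_years",
    "slope_pct",
    "altitude_m",
]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    input_digests: dict[str, str]
    seed: int
    version: str
    artifacts: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _mean_se(values) -> tuple[float, float, int]:
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    se = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(arr.mean()), se, n


def landuse_long_table(bundle: StudyBundle, profiles) -> pd.DataFrame:
    """One row per plot x interval with the stock and C % responses."""
    plots = bundle.plots.set_index("plot_id")
    rows = []
    for plot_id, prof in profiles.items():
        hz = bundle.horizons_of(plot_id).set_index("top_m")
        for iv in prof.intervals:
            rows.append(
                {
                    "plot_id": plot_id,
                    "cluster_id": plots.loc[plot_id, "cluster_id"],
                    "land_use": plots.loc[plot_id, "land_use"],
                    "interval": iv.label,
                    "stock": prof[iv],
                    "c_pct": float(hz.loc[iv.top_m, "c_pct"]),
                }
            )
    return pd.DataFrame(rows)


def _characteristics_table(bundle: StudyBundle) -> pd.DataFrame:
    hz = bundle.horizons.copy()
    hz["cn_ratio"] = hz["c_pct"] / hz["n_pct"]
    hz["interval"] = [
        f"{t:g}-{b:g}" for t, b in zip(hz["top_m"], hz["bottom_m"])
    ]
    plots = bundle.plots.set_index("plot_id")
    hz["land_use"] = hz["plot_id"].map(plots["land_use"])
    rows = []
    for col, label in CHARACTERISTIC_COLUMNS.items():
        for (land_use, interval), grp in hz.groupby(["land_use", "interval"]):
            mean, se, n = _mean_se(grp[col])
            if n == 0:
                continue
            rows.append(
                {"characteristic": label, "interval": interval,
                 "land_use": land_use, "mean": mean, "se": se, "n": n}
            )
    return pd.DataFrame(rows)


def _litter_trees_table(bundle: StudyBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    plots = bundle.plots.set_index("plot_id")
    per_plot = []
    for plot_id in bundle.plots["plot_id"]:
        lit = litter_stock(bundle.litter[bundle.litter["plot_id"] == plot_id])
        tree_ba, total_ba = basal_areas(
            bundle.trees[bundle.trees["plot_id"] == plot_id],
            float(plots.loc[plot_id, "plot_area_m2"]),
        )
        per_plot.append(
            {"plot_id": plot_id, "land_use": plots.loc[plot_id, "land_use"],
             "cluster_id": plots.loc[plot_id, "cluster_id"],
             "litter_c_stock": lit["stock_mg_ha"], "litter_c_pct": lit["c_pct_mean"],
             "litter_cn": lit["cn_ratio"], "tree_basal_area": tree_ba,
             "total_basal_area": total_ba}
        )
    per_plot = pd.DataFrame(per_plot)
    rows = []
    for col in ("litter_c_pct", "litter_cn", "litter_c_stock",
                "tree_basal_area", "total_basal_area"):
        for land_use, grp in per_plot.groupby("land_use"):
            mean, se, n = _mean_se(grp[col])
            rows.append(
                {"characteristic": col, "land_use": land_use,
                 "mean": mean, "se": se, "n": n}
            )
    return pd.DataFrame(rows), per_plot


def _stocks_changes_table(bundle, profiles, changes, variance_by):
    summary = summarize_changes(changes)
    long = landuse_long_table(bundle, profiles)
    plots = bundle.plots.set_index("plot_id")

    # Mixed-model per-depth significance of the stock response.
    results = LandUseMixedModel(long, "stock", variance_by=variance_by).fit()
    contrast_by_iv = {c.interval: c for c in results.contrasts()}

    rows = []
    for _, srow in summary.iterrows():
        iv = srow["interval"]
        if iv == "total":
            rub = long[long["land_use"] == "rubber"].groupby("plot_id")["stock"].sum()
            for_ = long[long["land_use"] == "forest"].groupby("plot_id")["stock"].sum()
            c_rub = c_for = (float("nan"), float("nan"))
            p_holm, stars = float("nan"), ""
        else:
            sel = long[long["interval"] == iv]
            rub = sel.loc[sel["land_use"] == "rubber", "stock"]
            for_ = sel.loc[sel["land_use"] == "forest", "stock"]
            c_rub = _mean_se(sel.loc[sel["land_use"] == "rubber", "c_pct"])[:2]
            c_for = _mean_se(sel.loc[sel["land_use"] == "forest", "c_pct"])[:2]
            con = contrast_by_iv[iv]
            p_holm, stars = con.p_holm, con.stars
        rub_m, rub_se, n_rub = _mean_se(rub)
        for_m, for_se, n_for = _mean_se(for_)
        rows.append(
            {"interval": iv,
             "rubber_c_pct": c_rub[0], "rubber_c_pct_se": c_rub[1],
             "rubber_stock": rub_m, "rubber_stock_se": rub_se, "n_rubber": n_rub,
             "forest_c_pct": c_for[0], "forest_c_pct_se": c_for[1],
             "forest_stock": for_m, "forest_stock_se": for_se, "n_forest": n_for,
             "abs_diff": srow["abs_mean"], "abs_diff_se": srow["abs_se"],
             "rel_diff_pct": srow["rel_mean"], "rel_diff_se": srow["rel_se"],
             "n_clusters": srow["n"], "p_holm": p_holm, "signif": stars}
        )
    table = pd.DataFrame(rows)

    # A total-profile paired test: mixed model on plot totals (depth collapses).
    totals = long.groupby(["plot_id"], sort=False).agg(
        stock=("stock", "sum"),
        cluster_id=("cluster_id", "first"),
        land_use=("land_use", "first"),
    ).reset_index()
    totals["interval"] = "total"
    tot_res = LandUseMixedModel(totals, "stock").fit()
    con = tot_res.contrasts(holm=False)[0]
    table.loc[table["interval"] == "total", "p_holm"] = con.p_raw
    table.loc[table["interval"] == "total", "signif"] = significance_stars(con.p_raw)
    return table, results


def _correlations_table(bundle, profiles, per_plot_stand, pairing_level):
    plots = bundle.plots.set_index("plot_id")
    hz = bundle.horizons.copy()
    hz["interval"] = [f"{t:g}-{b:g}" for t, b in zip(hz["top_m"], hz["bottom_m"])]
    stand = per_plot_stand.set_index("plot_id")
    cov = pd.DataFrame(
        {
            "litter_c_stock": stand["litter_c_stock"],
            "litter_cn": stand["litter_cn"],
            "total_basal_area": stand["total_basal_area"],
            "age_years": plots["age_years"],
            "slope_pct": plots["slope_pct"],
            "altitude_m": plots["altitude_m"],
        }
    )
    rel = plotwise_relative_differences(bundle, profiles)
    rows = []
    screen_intervals = [iv.label for iv in FITTED_INTERVALS]
    for iv in screen_intervals:
        hz_iv = hz[hz["interval"] == iv].set_index("plot_id")
        cov_iv = cov.join(hz_iv["silt_clay_pct"])
        for land_use in ("rubber", "forest"):
            ids = plots.index[plots["land_use"] == land_use]
            responses = hz_iv.loc[hz_iv.index.intersection(ids), ["c_pct"]]
            cov_use = cov_iv if land_use == "rubber" else cov_iv.drop(columns=["age_years"])
            for row in spearman_screen(responses, cov_use):
                rows.append(
                    {"response": f"{land_use}_c_pct", "interval": iv,
                     "covariate": row.covariate, "rho": row.rho,
                     "p_value": row.p_value, "n": row.n, "signif": row.stars}
                )
        rel_iv = rel[rel["interval"] == iv].set_index("plot_id")[["rel_diff_pct"]]
        if pairing_level == "cluster":
            rel_cl = rel[rel["interval"] == iv].groupby("cluster_id")["rel_diff_pct"].mean()
            cov_cl = cov_iv.join(plots["cluster_id"]).groupby("cluster_id").mean(numeric_only=True)
            resp_frame = rel_cl.to_frame()
            cov_frame = cov_cl
        else:
            resp_frame = rel_iv
            cov_frame = cov_iv
        for row in spearman_screen(resp_frame, cov_frame):
            rows.append(
                {"response": "rel_stock_diff", "interval": iv,
                 "covariate": row.covariate, "rho": row.rho,
                 "p_value": row.p_value, "n": row.n, "signif": row.stars}
            )
    return pd.DataFrame(rows)


def _decay_tables(bundle, profiles, fit_intervals, threshold, seed, log):
    fit_rows, curve_rows = [], []
    fits = {}
    for iv in fit_intervals:
        pts = proportions(bundle, profiles, iv)
        mono = SoilCarbonDecayModel.from_points(pts, kind="mono").fit(seed=seed)
        try:
            bi = SoilCarbonDecayModel.from_points(pts, kind="bi").fit(seed=seed)
            sel = select_model(mono, bi, identity_threshold_pct=threshold)
        except Exception as exc:  # bi fit unavailable -> keep mono
            sel = None
            log.append(f"decay[{iv.label}]: bi fit unavailable ({exc}); kept mono")
        chosen = sel.chosen if sel is not None else mono
        if sel is not None:
            log.append(f"decay[{iv.label}]: selected {sel.model} ({'; '.join(sel.rationale)})")
        fits[iv.label] = mono
        row = {"interval": iv.label, "selected_model": chosen.model,
               "n": mono.nobs, "converged": mono.converged,
               "Xe": mono.params["Xe"], "Xe_se": mono.bse["Xe"],
               "k": mono.params["k"], "k_se": mono.bse["k"],
               "r": mono.r, "r_pvalue": mono.r_pvalue,
               "steady_state_t": mono.steady_state_t}
        if sel is not None and sel.chosen.model == "bi":
            for name in ("X1", "k1", "k2"):
                row[name] = bi.params[name]
                row[f"{name}_se"] = bi.bse[name]
        fit_rows.append(row)
        grid = np.linspace(0, max(float(pts["t"].max()), 50.0), 101)
        pred = mono.predict(grid)
        for t, y in zip(grid, pred):
            curve_rows.append({"interval": iv.label, "t": t, "y_mono": y})
    return pd.DataFrame(fit_rows), pd.DataFrame(curve_rows), fits


def _bd_comparison_table(bundle):
    corrected = bundle_stock_profiles(bundle, bd_correction=True)
    uncorrected = bundle_stock_profiles(bundle, bd_correction=False)
    ch_c = bundle_cluster_changes(bundle, corrected)
    ch_u = bundle_cluster_changes(bundle, uncorrected)
    rows = []
    for cc, cu in zip(ch_c, ch_u):
        for iv in sorted(cc.absolute):
            rows.append(
                {"cluster_id": cc.cluster_id, "interval": iv.label,
                 "abs_corrected": cc.absolute[iv], "abs_uncorrected": cu.absolute[iv],
                 "rel_corrected": cc.relative[iv], "rel_uncorrected": cu.relative[iv]}
            )
        rows.append(
            {"cluster_id": cc.cluster_id, "interval": "total",
             "abs_corrected": cc.total_absolute, "abs_uncorrected": cu.total_absolute,
             "rel_corrected": cc.total_relative, "rel_uncorrected": cu.total_relative}
        )
    return pd.DataFrame(rows)


def analyze_bundle(bundle: StudyBundle, config: RunConfig | None = None) -> dict:
    """Run every analysis stage on a validated bundle; returns the tables."""
    cfg = config or RunConfig()
    log: list[str] = []
    profiles = bundle_stock_profiles(bundle, bd_correction=cfg.bd_correction)
    log.append(
        f"stocks: {len(profiles)} profiles, bd_correction={cfg.bd_correction}"
    )
    changes = bundle_cluster_changes(bundle, profiles)
    characteristics = _characteristics_table(bundle)
    litter_trees, per_plot_stand = _litter_trees_table(bundle)
    stocks_changes, lme_results = _stocks_changes_table(
        bundle, profiles, changes, cfg.variance_by
    )
    log.append(
        "landuse: stock mixed model "
        + ("with per-" + cfg.variance_by + " residual variances"
           if cfg.variance_by else "homoscedastic")
    )
    correlations = _correlations_table(bundle, profiles, per_plot_stand, cfg.pairing_level)
    fit_ivs = FITTED_INTERVALS if cfg.fit_intervals == "topsoil" else CANONICAL_INTERVALS
    decay_fits, decay_curves, fits = _decay_tables(
        bundle, profiles, fit_ivs, cfg.curve_identity_threshold_pct, cfg.seed, log
    )
    bd_comparison = _bd_comparison_table(bundle)
    return {
        "summary_characteristics": characteristics,
        "litter_trees": litter_trees,
        "stocks_changes": stocks_changes,
        "correlations": correlations,
        "decay_fits": decay_fits,
        "decay_curves": decay_curves,
        "bd_correction_comparison": bd_comparison,
        "_profiles": profiles,
        "_changes": changes,
        "_mono_fits": fits,
        "_lme_results": lme_results,
        "_per_plot_stand": per_plot_stand,
        "_log": log,
    }


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict]:
    """Full run: load or generate inputs, analyse, write report tables."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_digests: dict[str, str] = {}
    if config.input_dir:
        bundle = read_study(config.input_dir)
        for name in ("plots", "horizons", "litter", "trees"):
            input_digests[name] = _sha256(Path(config.input_dir) / f"{name}.csv")
    else:
        synth_cfg = SyntheticStudyConfig(**(config.synthetic or {}))
        bundle, _ = generate_study(synth_cfg, seed=config.seed)
        input_digests["synthetic_config"] = hashlib.sha256(
            json.dumps(synth_cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()

    tables = analyze_bundle(bundle, config)

    artifacts = []
    for name in ("summary_characteristics", "litter_trees", "stocks_changes",
                 "correlations", "decay_fits", "decay_curves",
                 "bd_correction_comparison"):
        path = out_dir / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        artifacts.append(path.name)

    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        input_digests=input_digests,
        seed=config.seed,
        version=__version__,
        artifacts=artifacts,
        log=tables["_log"],
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    manifest.artifacts.append("manifest.json")
    return manifest, tables
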
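"""Soil, litter and stand-level carbon stock accounting.

The central quantity is the soil organic carbon (SOC) stock of a depth
interval,

    stock [Mg C ha^-1] = (C% / 100) * BD [g cm^-3] * D [m] * 10^4,

with BD the bulk density and D the interval thickness; a bulk density of
1 g cm^-3 equals 1 Mg m^-3, so the factor 10^4 m^2 ha^-1 carries the product
to Mg C per hectare. Profile totals are sums over the depth intervals.

Because land-use change alters bulk density, converted plots are evaluated at
the *reference* (paired forest) bulk density: the converted plot's own carbon
concentration multiplied by the forest BD profile, so equal soil masses are
compared ("equal-BD" correction). Gravel is not corrected for.

Cluster-level change statistics follow the paired design: within each cluster
the rubber-plantation plots are averaged first, the forest is subtracted, and
relative changes are expressed as a percentage of the forest stock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import (
    ConfigurationError,
    DepthInterval,
    StudyBundle,
)

__all__ = [
    "StockProfile",
    "ClusterChange",
    "interval_stock",
    "profile_stocks",
    "bundle_stock_profiles",
    "cluster_changes",
    "summarize_changes",
    "loss_partition",
    "litter_stock",
    "basal_areas",
    "plotwise_relative_differences",
]

#: Unit constant of the stock equation: %C x g cm^-3 x m -> Mg C ha^-1.
_STOCK_FACTOR = 100.0


def interval_stock(c_pct: float, bd_g_cm3: float, interval: DepthInterval) -> float:
    """SOC stock (Mg C ha^-1) of one depth interval.

    Linear separately in ``c_pct`` and ``bd_g_cm3``.
    """
    if c_pct < 0:
        raise ValueError(f"c_pct must be non-negative, got {c_pct}")
    if bd_g_cm3 <= 0:
        raise ValueError(f"bd_g_cm3 must be positive, got {bd_g_cm3}")
    return c_pct * bd_g_cm3 * interval.thickness_m * _STOCK_FACTOR


@dataclass
class StockProfile:
    """Per-interval and total SOC stocks (Mg C ha^-1) for one plot."""

    plot_id: object
    stocks: dict[DepthInterval, float]
    bd_source: str  # "own" | "reference"

    @property
    def total(self) -> float:
        return float(sum(self.stocks.values()))

    def __getitem__(self, interval: DepthInterval) -> float:
        return self.stocks[interval]

    @property
    def intervals(self) -> list[DepthInterval]:
        return sorted(self.stocks)


def profile_stocks(
    plot_horizons: pd.DataFrame,
    reference_bd: dict[DepthInterval, float] | None = None,
    *,
    plot_id=None,
) -> StockProfile:
    """Compute a plot's stock profile from its horizon rows.

    ``reference_bd`` maps each interval to the paired forest plot's bulk
    density; when given, stocks use the plot's own C % with the reference BD
    (``bd_source="reference"``). When ``None``, the plot's own BD is used.
    """
    if plot_id is None:
        plot_id = plot_horizons["plot_id"].iloc[0]
    stocks: dict[DepthInterval, float] = {}
    for row in plot_horizons.itertuples(index=False):
        interval = DepthInterval(float(row.top_m), float(row.bottom_m))
        bd = float(row.bd_g_cm3)
        if reference_bd is not None:
            if interval not in reference_bd:
                raise ConfigurationError(
                    f"plot {plot_id!r}: no reference bulk density for interval {interval}"
                )
            bd = reference_bd[interval]
        stocks[interval] = interval_stock(float(row.c_pct), bd, interval)
    return StockProfile(
        plot_id=plot_id,
        stocks=stocks,
        bd_source="own" if reference_bd is None else "reference",
    )


def bundle_stock_profiles(
    bundle: StudyBundle, *, bd_correction: bool = True
) -> dict[object, StockProfile]:
    """Stock profiles for every plot in a study.

    Forest plots always use their own BD. Rubber plots use the same-cluster
    forest BD profile unless ``bd_correction=False`` (the uncorrected variant,
    kept only for quantifying the error the correction removes).
    """
    plots = bundle.plots.set_index("plot_id")
    forest_bd: dict[object, dict[DepthInterval, float]] = {}
    for cluster_id in bundle.clusters:
        forest_plot = bundle.plots_of(cluster_id, "forest")["plot_id"].iloc[0]
        hz = bundle.horizons_of(forest_plot)
        forest_bd[cluster_id] = {
            DepthInterval(float(r.top_m), float(r.bottom_m)): float(r.bd_g_cm3)
            for r in hz.itertuples(index=False)
        }
    profiles: dict[object, StockProfile] = {}
    for plot_id, hz in bundle.horizons.groupby("plot_id", sort=False):
        land_use = plots.loc[plot_id, "land_use"]
        ref = None
        if land_use == "rubber" and bd_correction:
            ref = forest_bd[plots.loc[plot_id, "cluster_id"]]
        profiles[plot_id] = profile_stocks(hz, ref, plot_id=plot_id)
    return profiles


@dataclass
class ClusterChange:
    """Paired stock changes (rubber mean minus forest) for one cluster.

    ``relative`` entries are percentages of the forest stock; they are None
    where the forest stock is zero.
    """

    cluster_id: object
    absolute: dict[DepthInterval, float]
    relative: dict[DepthInterval, float | None]
    total_absolute: float
    total_relative: float | None
    n_rubber: int = field(default=1)


def cluster_changes(
    forest: StockProfile, rubber: list[StockProfile], *, cluster_id=None
) -> ClusterChange:
    """Per-cluster absolute and relative stock differences.

    Rubber plots are averaged per interval *before* differencing, so each
    cluster contributes one paired change regardless of how many plantations
    it holds.
    """
    if not rubber:
        raise ValueError("cluster_changes requires at least one rubber profile")
    intervals = forest.intervals
    for prof in rubber:
        if prof.intervals != intervals:
            raise ValueError(
                f"profile {prof.plot_id!r} depth set differs from forest profile"
            )
    absolute: dict[DepthInterval, float] = {}
    relative: dict[DepthInterval, float | None] = {}
    for iv in intervals:
        rubber_mean = float(np.mean([p[iv] for p in rubber]))
        diff = rubber_mean - forest[iv]
        absolute[iv] = diff
        relative[iv] = 100.0 * diff / forest[iv] if forest[iv] != 0 else None
    total_abs = float(np.mean([p.total for p in rubber])) - forest.total
    total_rel = 100.0 * total_abs / forest.total if forest.total != 0 else None
    return ClusterChange(
        cluster_id=cluster_id,
        absolute=absolute,
        relative=relative,
        total_absolute=total_abs,
        total_relative=total_rel,
        n_rubber=len(rubber),
    )


def bundle_cluster_changes(
    bundle: StudyBundle, profiles: dict[object, StockProfile]
) -> list[ClusterChange]:
    """Cluster changes for every cluster of a study, in cluster order."""
    changes = []
    for cluster_id in bundle.clusters:
        forest_id = bundle.plots_of(cluster_id, "forest")["plot_id"].iloc[0]
        rubber_ids = bundle.plots_of(cluster_id, "rubber")["plot_id"].tolist()
        changes.append(
            cluster_changes(
                profiles[forest_id],
                [profiles[i] for i in rubber_ids],
                cluster_id=cluster_id,
            )
        )
    return changes


def summarize_changes(changes: list[ClusterChange]) -> pd.DataFrame:
    """Mean +/- SE over clusters of the paired changes, per interval and total.

    Returns a tidy frame with one row per depth interval plus a ``total`` row,
    columns ``abs_mean, abs_se, rel_mean, rel_se, n`` (n = clusters). SE is the
    standard error of the mean (ddof=1).
    """
    if len(changes) < 2:
        raise ValueError("summarize_changes requires at least two clusters")
    intervals = sorted(changes[0].absolute)
    rows = []

    def _mean_se(values):
        arr = np.asarray([v for v in values if v is not None], dtype=float)
        n = arr.size
        se = float(np.std(arr, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        return float(arr.mean()), se, n

    for iv in intervals:
        am, ase, n = _mean_se([c.absolute[iv] for c in changes])
        rm, rse, _ = _mean_se([c.relative[iv] for c in changes])
        rows.append(
            {"interval": iv.label, "abs_mean": am, "abs_se": ase,
             "rel_mean": rm, "rel_se": rse, "n": n}
        )
    am, ase, n = _mean_se([c.total_absolute for c in changes])
    rm, rse, _ = _mean_se([c.total_relative for c in changes])
    rows.append(
        {"interval": "total", "abs_mean": am, "abs_se": ase,
         "rel_mean": rm, "rel_se": rse, "n": n}
    )
    return pd.DataFrame(rows)


def loss_partition(abs_changes: dict[DepthInterval, float]) -> dict[str, float]:
    """Partition a mean absolute change profile into depth shares.

    Returns the percentage share of the total absolute change held by the top
    interval (``top_share_pct``) and the summed change of the upper 0.3 m
    (``top30_abs``); helpers for reading a change table as "where the loss
    sits" in the profile.
    """
    intervals = sorted(abs_changes)
    total = sum(abs_changes.values())
    if total == 0:
        raise ValueError("total change is zero; shares undefined")
    top = abs_changes[intervals[0]]
    top30 = sum(abs_changes[iv] for iv in intervals if iv.bottom_m <= 0.3 + 1e-9)
    return {
        "top_share_pct": 100.0 * abs(top) / abs(total),
        "top30_abs": top30,
    }


def litter_stock(litter_records: pd.DataFrame) -> dict[str, float]:
    """Litter-layer carbon stock of one plot from its frame samples.

    Each sample contributes (C%/100) x dry mass scaled from the frame area to
    one hectare; the plot value is the mean over samples (10 frames in the
    reference design). Returns the stock with its SE plus mean C % and C:N.
    """
    if litter_records.empty:
        raise ValueError("litter_stock requires at least one sample")
    frame = litter_records["frame_area_m2"].astype(float)
    if (frame <= 0).any():
        raise ValueError("frame_area_m2 must be positive")
    mass = litter_records["mass_g"].astype(float)
    c_pct = litter_records["c_pct"].astype(float)
    n_pct = litter_records["n_pct"].astype(float)
    # g C m^-2 -> Mg C ha^-1 is a factor 0.01 (10^4 m^2 / 10^6 g).
    per_sample = (c_pct / 100.0) * mass / frame * 0.01
    n = len(per_sample)
    se = float(per_sample.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = float((c_pct / n_pct).mean())
    return {
        "stock_mg_ha": float(per_sample.mean()),
        "stock_se": se,
        "c_pct_mean": float(c_pct.mean()),
        "cn_ratio": cn,
        "n_samples": n,
    }


def basal_areas(tree_records: pd.DataFrame, plot_area_m2: float) -> tuple[float, float]:
    """(tree basal area, total basal area) in m^2 ha^-1 for one plot.

    Per-stem basal area is pi (dbh/200)^2 with dbh in cm; a bamboo clump
    contributes its stem count times the basal area of the measured stem.
    Tree basal area excludes bamboo, total includes it.
    """
    if plot_area_m2 <= 0:
        raise ValueError("plot_area_m2 must be positive")
    if tree_records.empty:
        return (0.0, 0.0)
    dbh = tree_records["dbh_cm"].astype(float)
    stems = tree_records["stems_in_clump"].astype(float)
    per_stem = np.pi * (dbh / 200.0) ** 2
    contrib = per_stem * stems
    scale = 10_000.0 / plot_area_m2
    is_tree = tree_records["stem_kind"] == "tree"
    tree_ba = float(contrib[is_tree].sum() * scale)
    total_ba = float(contrib.sum() * scale)
    return (tree_ba, total_ba)


def plotwise_relative_differences(
    bundle: StudyBundle, profiles: dict[object, StockProfile]
) -> pd.DataFrame:
    """Per rubber *plot* relative stock differences vs. its cluster's forest.

    100 x (rubber - forest) / forest per interval, one row per rubber plot and
    interval plus a ``total`` row — the plot-level pairing used by the
    covariate correlation screen (the cluster-level pairing used for the
    change summary lives in :func:`cluster_changes`).
    """
    plots = bundle.plots.set_index("plot_id")
    rows = []
    for cluster_id in bundle.clusters:
        forest_id = bundle.plots_of(cluster_id, "forest")["plot_id"].iloc[0]
        fprof = profiles[forest_id]
        for rubber_id in bundle.plots_of(cluster_id, "rubber")["plot_id"]:
            rprof = profiles[rubber_id]
            for iv in fprof.intervals:
                denom = fprof[iv]
                rows.append(
                    {
                        "plot_id": rubber_id,
                        "cluster_id": cluster_id,
                        "age_years": float(plots.loc[rubber_id, "age_years"]),
                        "interval": iv.label,
                        "rel_diff_pct": (
                            100.0 * (rprof[iv] - denom) / denom if denom else np.nan
                        ),
                    }
                )
            rows.append(
                {
                    "plot_id": rubber_id,
                    "cluster_id": cluster_id,
                    "age_years": float(plots.loc[rubber_id, "age_years"]),
                    "interval": "total",
                    "rel_diff_pct": (
                        100.0 * (rprof.total - fprof.total) / fprof.total
                        if fprof.total
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
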
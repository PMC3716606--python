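"""Input tables, validation, and the study bundle.

A *study* is a clustered, paired land-use comparison: spatial clusters each
holding one reference secondary-forest plot and one to three rubber-plantation
plots of known age, sampled over a fixed set of depth intervals down to 1.2 m.
Four plain CSV tables describe a study:

``plots.csv``
    plot_id,cluster_id,land_use,age_years,altitude_m,slope_pct,plot_area_m2
``horizons.csv``
    plot_id,top_m,bottom_m,c_pct,n_pct,bd_g_cm3,sand_pct,silt_clay_pct,
    ph_h2o,ph_kcl,ecec_mmolc_kg,base_sat_pct
``litter.csv``
    plot_id,sample_id,mass_g,frame_area_m2,c_pct,n_pct
``trees.csv``
    plot_id,stem_kind,dbh_cm,stems_in_clump

All downstream modules consume only the validated :class:`StudyBundle`.
Optional chemistry columns may be blank; blanks propagate as missing values,
never as zeros.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DepthInterval",
    "CANONICAL_INTERVALS",
    "StudyBundle",
    "StudyValidationError",
    "SchemaError",
    "DesignError",
    "ProfileError",
    "ConfigurationError",
    "read_study",
    "write_study",
    "load_run_config",
]


class StudyValidationError(ValueError):
    """Base class for all study-validation failures."""


class SchemaError(StudyValidationError):
    """A table is missing a required column or holds an out-of-range value."""


class DesignError(StudyValidationError):
    """The plot table violates the clustered paired design."""


class ProfileError(StudyValidationError):
    """A plot's depth intervals have gaps, overlaps, or a non-canonical set."""


class ConfigurationError(StudyValidationError):
    """An analysis or generator configuration is unusable."""


@dataclass(frozen=True, order=True)
class DepthInterval:
    """Half-open depth interval [top_m, bottom_m) in meters below the surface."""

    top_m: float
    bottom_m: float

    def __post_init__(self) -> None:
        if not (0 <= self.top_m < self.bottom_m):
            raise ProfileError(
                f"invalid depth interval [{self.top_m}, {self.bottom_m})"
            )

    @property
    def thickness_m(self) -> float:
        return self.bottom_m - self.top_m

    @property
    def label(self) -> str:
        return f"{self.top_m:g}-{self.bottom_m:g}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


#: The canonical five-interval profile down to 1.2 m.
CANONICAL_INTERVALS: tuple[DepthInterval, ...] = (
    DepthInterval(0.0, 0.15),
    DepthInterval(0.15, 0.3),
    DepthInterval(0.3, 0.6),
    DepthInterval(0.6, 0.9),
    DepthInterval(0.9, 1.2),
)

#: Topsoil intervals for which decay curves are conventionally fitted.
FITTED_INTERVALS: tuple[DepthInterval, ...] = CANONICAL_INTERVALS[:3]

PLOT_COLUMNS = [
    "plot_id",
    "cluster_id",
    "land_use",
    "age_years",
    "altitude_m",
    "slope_pct",
    "plot_area_m2",
]
HORIZON_COLUMNS = [
    "plot_id",
    "top_m",
    "bottom_m",
    "c_pct",
    "n_pct",
    "bd_g_cm3",
    "sand_pct",
    "silt_clay_pct",
    "ph_h2o",
    "ph_kcl",
    "ecec_mmolc_kg",
    "base_sat_pct",
]
HORIZON_REQUIRED = HORIZON_COLUMNS[:8]
LITTER_COLUMNS = ["plot_id", "sample_id", "mass_g", "frame_area_m2", "c_pct", "n_pct"]
TREE_COLUMNS = ["plot_id", "stem_kind", "dbh_cm", "stems_in_clump"]

DEFAULT_PLOT_AREA_M2 = 400.0  # 20 x 20 m, slope-corrected
DEFAULT_FRAME_AREA_M2 = 0.04
FOREST_DBH_THRESHOLD_CM = 4.0


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


@dataclass
class StudyBundle:
    """Validated in-memory form of one study.

    The four tables are pandas DataFrames with the documented columns; rows
    are sorted canonically (by plot, then depth / sample) so that two bundles
    built from row-shuffled files compare equal.
    """

    plots: pd.DataFrame
    horizons: pd.DataFrame
    litter: pd.DataFrame
    trees: pd.DataFrame

    @property
    def clusters(self) -> list:
        return sorted(self.plots["cluster_id"].unique().tolist())

    @property
    def intervals(self) -> list[DepthInterval]:
        pairs = (
            self.horizons[["top_m", "bottom_m"]]
            .drop_duplicates()
            .sort_values("top_m")
            .itertuples(index=False)
        )
        return [DepthInterval(t, b) for t, b in pairs]

    def plots_of(self, cluster_id, land_use: str | None = None) -> pd.DataFrame:
        sel = self.plots[self.plots["cluster_id"] == cluster_id]
        if land_use is not None:
            sel = sel[sel["land_use"] == land_use]
        return sel

    def horizons_of(self, plot_id) -> pd.DataFrame:
        return self.horizons[self.horizons["plot_id"] == plot_id]

    def equals(self, other: "StudyBundle") -> bool:
        return all(
            getattr(self, name).reset_index(drop=True).equals(
                getattr(other, name).reset_index(drop=True)
            )
            for name in ("plots", "horizons", "litter", "trees")
        )


def _validate_plots(plots: pd.DataFrame, age_range: tuple[float, float]) -> pd.DataFrame:
    _require_columns(plots, PLOT_COLUMNS, "plots")
    plots = plots.copy()
    if plots.empty:
        raise SchemaError("plots: table is empty")
    if plots["plot_id"].duplicated().any():
        dup = plots.loc[plots["plot_id"].duplicated(), "plot_id"].iloc[0]
        raise SchemaError(f"plots: duplicate plot_id {dup!r}")
    bad_use = set(plots["land_use"]) - {"forest", "rubber"}
    if bad_use:
        raise SchemaError(f"plots: unknown land_use value(s) {sorted(bad_use)}")
    for cluster_id, grp in plots.groupby("cluster_id"):
        n_forest = int((grp["land_use"] == "forest").sum())
        n_rubber = int((grp["land_use"] == "rubber").sum())
        if n_forest != 1:
            raise DesignError(
                f"cluster {cluster_id!r}: expected exactly 1 forest plot, found {n_forest}"
            )
        if not (1 <= n_rubber <= 3):
            raise DesignError(
                f"cluster {cluster_id!r}: expected 1-3 rubber plots, found {n_rubber}"
            )
    rubber = plots[plots["land_use"] == "rubber"]
    ages = pd.to_numeric(rubber["age_years"], errors="coerce")
    if ages.isna().any():
        bad = rubber.loc[ages.isna(), "plot_id"].tolist()
        raise SchemaError(f"plots: rubber plot(s) {bad} lack a numeric age_years")
    lo, hi = age_range
    off = rubber.loc[(ages < lo) | (ages > hi), "plot_id"].tolist()
    if off:
        raise SchemaError(
            f"plots: rubber age outside plausible range [{lo}, {hi}] for {off}"
        )
    if (pd.to_numeric(plots["plot_area_m2"]) <= 0).any():
        raise SchemaError("plots: plot_area_m2 must be positive")
    return plots.sort_values("plot_id", kind="mergesort").reset_index(drop=True)


def _validate_horizons(
    horizons: pd.DataFrame,
    plot_ids: set,
    intervals: tuple[DepthInterval, ...],
) -> pd.DataFrame:
    if "silt_pct" in horizons.columns and "clay_pct" in horizons.columns and (
        "silt_clay_pct" not in horizons.columns
    ):
        horizons = horizons.copy()
        horizons["silt_clay_pct"] = pd.to_numeric(
            horizons["silt_pct"]
        ) + pd.to_numeric(horizons["clay_pct"])
        horizons = horizons.drop(columns=["silt_pct", "clay_pct"])
    _require_columns(horizons, HORIZON_REQUIRED, "horizons")
    horizons = horizons.copy()
    for col in HORIZON_COLUMNS:
        if col not in horizons.columns:
            horizons[col] = np.nan
    horizons = horizons[HORIZON_COLUMNS]
    if horizons.empty:
        raise SchemaError("horizons: table is empty")
    unknown = set(horizons["plot_id"]) - plot_ids
    if unknown:
        raise SchemaError(f"horizons: plot_id(s) without a plot record: {sorted(unknown)}")

    num = horizons.assign(
        c_pct=pd.to_numeric(horizons["c_pct"]),
        bd=pd.to_numeric(horizons["bd_g_cm3"]),
        sand=pd.to_numeric(horizons["sand_pct"]),
        sc=pd.to_numeric(horizons["silt_clay_pct"]),
    )
    if ((num["c_pct"] < 0) | (num["c_pct"] > 60)).any():
        bad = num.loc[(num["c_pct"] < 0) | (num["c_pct"] > 60), "plot_id"].tolist()
        raise SchemaError(f"horizons: c_pct outside [0, 60] for plot(s) {bad}")
    if ((num["bd"] < 0.2) | (num["bd"] > 2.2)).any():
        bad = num.loc[(num["bd"] < 0.2) | (num["bd"] > 2.2), "plot_id"].tolist()
        raise SchemaError(f"horizons: bd_g_cm3 outside [0.2, 2.2] for plot(s) {bad}")
    tex = (num["sand"] + num["sc"] - 100).abs()
    if (tex.dropna() > 0.5).any():
        bad = num.loc[tex > 0.5, "plot_id"].tolist()
        raise SchemaError(
            f"horizons: sand_pct + silt_clay_pct differs from 100 by >0.5 for {bad}"
        )

    expected = sorted((iv.top_m, iv.bottom_m) for iv in intervals)
    for plot_id, grp in horizons.groupby("plot_id"):
        got = sorted(zip(grp["top_m"].astype(float), grp["bottom_m"].astype(float)))
        for (t1, b1), (t2, b2) in zip(got, got[1:]):
            if t2 < b1 - 1e-9:
                raise ProfileError(
                    f"plot {plot_id!r}: overlapping intervals {t1}-{b1} and {t2}-{b2}"
                )
        if len(got) != len(expected) or not np.allclose(
            np.asarray(got), np.asarray(expected), atol=1e-9
        ):
            raise ProfileError(
                f"plot {plot_id!r}: depth intervals {got} do not match the "
                f"canonical set {expected} (gap, overlap, or missing interval)"
            )
    return (
        horizons.sort_values(["plot_id", "top_m"], kind="mergesort")
        .reset_index(drop=True)
    )


def _validate_litter(litter: pd.DataFrame, plot_ids: set) -> pd.DataFrame:
    _require_columns(litter, LITTER_COLUMNS, "litter")
    litter = litter[LITTER_COLUMNS].copy()
    unknown = set(litter["plot_id"]) - plot_ids
    if unknown:
        raise SchemaError(f"litter: plot_id(s) without a plot record: {sorted(unknown)}")
    if (pd.to_numeric(litter["mass_g"]) < 0).any():
        raise SchemaError("litter: mass_g must be non-negative")
    if (pd.to_numeric(litter["frame_area_m2"]) <= 0).any():
        raise SchemaError("litter: frame_area_m2 must be positive")
    return (
        litter.sort_values(["plot_id", "sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def _validate_trees(trees: pd.DataFrame, plots: pd.DataFrame) -> pd.DataFrame:
    _require_columns(trees, TREE_COLUMNS, "trees")
    trees = trees[TREE_COLUMNS].copy()
    plot_ids = set(plots["plot_id"])
    unknown = set(trees["plot_id"]) - plot_ids
    if unknown:
        raise SchemaError(f"trees: plot_id(s) without a plot record: {sorted(unknown)}")
    bad_kind = set(trees["stem_kind"]) - {"tree", "bamboo_clump"}
    if bad_kind:
        raise SchemaError(f"trees: unknown stem_kind value(s) {sorted(bad_kind)}")
    if (pd.to_numeric(trees["dbh_cm"]) <= 0).any():
        raise SchemaError("trees: dbh_cm must be positive")
    if (pd.to_numeric(trees["stems_in_clump"]) < 1).any():
        raise SchemaError("trees: stems_in_clump must be >= 1")
    # Forest inventories only record trees above the DBH threshold; smaller
    # stems are dropped here rather than rejected (bamboo clumps are kept).
    land_use = plots.set_index("plot_id")["land_use"]
    is_forest = trees["plot_id"].map(land_use) == "forest"
    drop = (
        is_forest
        & (trees["stem_kind"] == "tree")
        & (pd.to_numeric(trees["dbh_cm"]) <= FOREST_DBH_THRESHOLD_CM)
    )
    trees = trees[~drop]
    return (
        trees.sort_values(["plot_id", "stem_kind", "dbh_cm"], kind="mergesort")
        .reset_index(drop=True)
    )


def assemble_study(
    plots: pd.DataFrame,
    horizons: pd.DataFrame,
    litter: pd.DataFrame,
    trees: pd.DataFrame,
    *,
    intervals: tuple[DepthInterval, ...] = CANONICAL_INTERVALS,
    age_range: tuple[float, float] = (1.0, 60.0),
) -> StudyBundle:
    """Validate the four raw tables and return a :class:`StudyBundle`.

    Validation is order-independent: row order in the inputs never changes
    acceptance or the resulting bundle.
    """
    plots = _validate_plots(plots, age_range)
    plot_ids = set(plots["plot_id"])
    horizons = _validate_horizons(horizons, plot_ids, intervals)
    litter = _validate_litter(litter, plot_ids)
    trees = _validate_trees(trees, plots)
    return StudyBundle(plots=plots, horizons=horizons, litter=litter, trees=trees)


def read_study(
    source: str | Path | Mapping[str, str | Path],
    *,
    intervals: tuple[DepthInterval, ...] = CANONICAL_INTERVALS,
    age_range: tuple[float, float] = (1.0, 60.0),
) -> StudyBundle:
    """Read and validate a study from a directory or a mapping of paths.

    ``source`` is either a directory containing ``plots.csv``, ``horizons.csv``,
    ``litter.csv`` and ``trees.csv``, or a mapping with keys
    ``plots/horizons/litter/trees``.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {name: base / f"{name}.csv" for name in ("plots", "horizons", "litter", "trees")}
    else:
        paths = {k: Path(v) for k, v in source.items()}
    tables = {}
    for name, path in paths.items():
        if not path.exists():
            raise SchemaError(f"{name}: file not found: {path}")
        try:
            tables[name] = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{name}: file {path} is empty") from exc
    return assemble_study(
        tables["plots"], tables["horizons"], tables["litter"], tables["trees"],
        intervals=intervals, age_range=age_range,
    )


def write_study(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV; re-reading yields an identical bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in ("plots", "horizons", "litter", "trees"):
        path = out / f"{name}.csv"
        # full-precision floats so the round-trip is exact
        getattr(bundle, name).to_csv(
            path, index=False, float_format=lambda x: repr(float(x))
        )
        written[name] = path
    return written


@dataclass
class RunConfig:
    """Options steering one pipeline run (parsed from the YAML run config)."""

    input_dir: str | None = None
    output_dir: str = "socchrono_out"
    seed: int = 0
    bd_correction: bool = True
    variance_by: str | None = None  # None | "land_use" | "interval"
    pairing_level: str = "plot"  # "plot" (n=11) or "cluster" (n=7)
    curve_identity_threshold_pct: float = 0.5
    fit_intervals: str = "topsoil"  # "topsoil" (upper three) or "all"
    synthetic: dict | None = None  # generator overrides when no input_dir

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"run config: unknown key(s) {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if cfg.variance_by not in (None, "land_use", "interval"):
        raise ConfigurationError(
            f"run config: variance_by must be null, 'land_use' or 'interval', got {cfg.variance_by!r}"
        )
    if cfg.pairing_level not in ("plot", "cluster"):
        raise ConfigurationError(
            f"run config: pairing_level must be 'plot' or 'cluster', got {cfg.pairing_level!r}"
        )
    return cfg
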
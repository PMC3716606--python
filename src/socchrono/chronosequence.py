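"""Chronosequence decay models for soil carbon after land-use change.

Under space-for-time substitution, plantations of different ages stand in for
one site observed through time. Each rubber plot contributes a point
(t, y): t the years since conversion and y the plot's SOC stock as a
percentage of its paired forest's stock. Two pool models are fitted by
nonlinear least squares, both anchored at X0 = 100 % at t = 0:

mono-exponential (single pool decaying to a new equilibrium Xe):

    X(t) = Xe + (X0 - Xe) * exp(-k t)

bi-exponential (labile pool X1 and stable pool X2 = X0 - X1):

    X(t) = X1 * exp(-k1 t) + (X0 - X1) * exp(-k2 t)

Goodness of fit is summarised by the Pearson correlation r between observed
and fitted values. For the mono model, the steady state is declared reached at
the first time t* where X(t*) - Xe <= 0.01 * Xe, which has the closed form

    t* = ln((X0 - Xe) / (0.01 Xe)) / k.

Model choice follows parsimony: the bi-exponential model is preferred only
when its decay rates are statistically distinguishable and its fitted curve
actually departs from the mono curve over the observed ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schemas import DepthInterval, StudyBundle
from .stocks import StockProfile

__all__ = [
    "mono_exp",
    "bi_exp",
    "proportions",
    "SoilCarbonDecayModel",
    "DecayResults",
    "fit_decay",
    "steady_state_time",
    "select_model",
    "ModelSelection",
    "FitError",
]

X0 = 100.0  # proportions are anchored at 100 % of the forest stock


class FitError(RuntimeError):
    """Raised when a fit cannot be attempted (e.g. too few points)."""


def mono_exp(t, xe, k):
    """Single-pool decay toward equilibrium: Xe + (100 - Xe) e^{-kt}."""
    t = np.asarray(t, dtype=float)
    return xe + (X0 - xe) * np.exp(-k * t)


def bi_exp(t, x1, k1, k2):
    """Two-pool decay: X1 e^{-k1 t} + (100 - X1) e^{-k2 t}."""
    t = np.asarray(t, dtype=float)
    return x1 * np.exp(-k1 * t) + (X0 - x1) * np.exp(-k2 * t)


def proportions(
    bundle: StudyBundle,
    profiles: dict[object, StockProfile],
    interval: DepthInterval,
) -> pd.DataFrame:
    """Proportion-remaining points for one depth interval.

    One row per rubber plot: ``t`` the plantation age and ``y`` the rubber
    stock as a percentage of the same-cluster forest stock. Plots whose forest
    stock is zero are dropped.
    """
    plots = bundle.plots.set_index("plot_id")
    rows = []
    for cluster_id in bundle.clusters:
        forest_id = bundle.plots_of(cluster_id, "forest")["plot_id"].iloc[0]
        forest_stock = profiles[forest_id][interval]
        for rubber_id in bundle.plots_of(cluster_id, "rubber")["plot_id"]:
            if forest_stock == 0:
                continue
            rows.append(
                {
                    "plot_id": rubber_id,
                    "cluster_id": cluster_id,
                    "t": float(plots.loc[rubber_id, "age_years"]),
                    "y": 100.0 * profiles[rubber_id][interval] / forest_stock,
                }
            )
    return pd.DataFrame(rows)


def steady_state_time(xe: float, k: float) -> float:
    """First time at which X(t) is within 1 % of Xe (mono model, closed form)."""
    if k <= 0:
        raise ValueError("no steady state: k must be positive")
    if not (0 < xe < X0):
        raise ValueError("no steady state: Xe must lie in (0, 100)")
    return math.log((X0 - xe) / (0.01 * xe)) / k


_MONO_BOUNDS = ([1e-9, 1e-9], [120.0, 5.0])
_BI_BOUNDS = ([0.0, 1e-9, 1e-9], [100.0, 5.0, 5.0])


@dataclass
class DecayResults:
    """Fitted decay model: estimates, uncertainties and diagnostics.

    ``params``/``bse``/``pvalues`` are indexed by parameter name
    (mono: Xe, k; bi: X1, k1, k2). P-values are Wald tests of each parameter
    against zero on n - p degrees of freedom; confidence intervals use the
    same t reference.
    """

    model: str
    params: pd.Series
    bse: pd.Series
    t: np.ndarray
    y: np.ndarray
    converged: bool
    n_restarts_used: int = 0
    df_resid: int = 0

    @property
    def nobs(self) -> int:
        return len(self.t)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.t)

    @property
    def resid(self) -> np.ndarray:
        return self.y - self.fittedvalues

    @property
    def ssr(self) -> float:
        return float(np.sum(self.resid ** 2))

    def predict(self, t) -> np.ndarray:
        p = self.params
        if self.model == "mono":
            return mono_exp(t, p["Xe"], p["k"])
        return bi_exp(t, p["X1"], p["k1"], p["k2"])

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        tv = np.abs(self.tvalues.to_numpy())
        return pd.Series(
            2 * stats.t.sf(tv, self.df_resid), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    @property
    def r(self) -> float:
        """Pearson correlation between observed and fitted values."""
        if np.ptp(self.fittedvalues) == 0 or np.ptp(self.y) == 0:
            return float("nan")
        return float(stats.pearsonr(self.y, self.fittedvalues).statistic)

    @property
    def r_pvalue(self) -> float:
        if np.ptp(self.fittedvalues) == 0 or np.ptp(self.y) == 0:
            return float("nan")
        return float(stats.pearsonr(self.y, self.fittedvalues).pvalue)

    @property
    def steady_state_t(self) -> float | None:
        """Steady-state time (years) for a converged mono fit; None otherwise."""
        if self.model != "mono" or not self.converged:
            return None
        xe, k = self.params["Xe"], self.params["k"]
        if k <= 0 or not (0 < xe < X0):
            return None
        return steady_state_time(xe, k)

    @property
    def steady_state_proportion(self) -> float | None:
        """Proportion remaining at the steady-state time."""
        t_star = self.steady_state_t
        if t_star is None:
            return None
        return float(self.predict(t_star))

    def summary(self) -> str:
        lines = [
            f"Decay model: {self.model}-exponential (X0 fixed at 100 %)",
            f"n = {self.nobs}, converged = {self.converged}, SSR = {self.ssr:.4g}",
            f"Pearson r(obs, fitted) = {self.r:.4f} (p = {self.r_pvalue:.3g})",
            "",
            f"{'param':>6} {'estimate':>10} {'SE':>10} {'t':>8} {'P>|t|':>9}",
        ]
        pv = self.pvalues
        for name in self.params.index:
            lines.append(
                f"{name:>6} {self.params[name]:>10.4f} {self.bse[name]:>10.4f} "
                f"{self.tvalues[name]:>8.3f} {pv[name]:>9.3g}"
            )
        if self.steady_state_t is not None:
            lines.append("")
            lines.append(
                f"steady state: t* = {self.steady_state_t:.2f} yr "
                f"(X(t*) = {self.steady_state_proportion:.2f} %)"
            )
        return "\n".join(lines)


class SoilCarbonDecayModel:
    """Nonlinear least-squares pool model for proportion-remaining points.

    Parameters
    ----------
    t, y : array-like
        Years since conversion and percentage of the paired forest stock.
    kind : {"mono", "bi"}
        Single-pool model with equilibrium (Xe, k) or two-pool model
        (X1, k1, k2) with X2 = 100 - X1.

    ``fit`` runs a small seeded multi-start around the default start values to
    reduce the risk of a local minimum, and reports asymptotic standard errors
    from the Jacobian at the solution.
    """

    def __init__(self, t, y, kind: str = "mono"):
        if kind not in ("mono", "bi"):
            raise ValueError(f"kind must be 'mono' or 'bi', got {kind!r}")
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if np.any(self.t < 0):
            raise ValueError("ages must be non-negative")
        self.kind = kind
        self._func = mono_exp if kind == "mono" else bi_exp
        self._names = ["Xe", "k"] if kind == "mono" else ["X1", "k1", "k2"]
        self._bounds = _MONO_BOUNDS if kind == "mono" else _BI_BOUNDS

    @classmethod
    def from_points(cls, points: pd.DataFrame, kind: str = "mono"):
        return cls(points["t"].to_numpy(), points["y"].to_numpy(), kind=kind)

    @property
    def n_params(self) -> int:
        return len(self._names)

    def default_start(self) -> np.ndarray:
        if self.kind == "mono":
            xe0 = max(float(np.min(self.y)), 1.0)
            return np.array([min(xe0, 119.0), 0.1])
        return np.array([30.0, 0.3, 0.01])

    def fit(
        self,
        start: Sequence[float] | None = None,
        *,
        n_restarts: int = 5,
        seed: int = 0,
        max_iter: int = 10_000,
        tol: float = 1e-10,
    ) -> DecayResults:
        """Fit by least squares with jittered multi-starts; never raises on
        non-convergence (``converged=False`` instead)."""
        if len(self.t) < self.n_params + 1:
            raise FitError(
                f"{self.kind} model needs at least {self.n_params + 1} points, "
                f"got {len(self.t)}"
            )
        start0 = np.asarray(start, dtype=float) if start is not None else self.default_start()
        lo, hi = (np.asarray(b, dtype=float) for b in self._bounds)
        rng = np.random.default_rng(seed)
        starts = [start0]
        for _ in range(n_restarts):
            jitter = start0 * rng.uniform(0.5, 1.8, size=start0.shape)
            starts.append(np.clip(jitter, lo + 1e-8, hi - 1e-8))

        best = None
        used = 0
        for i, s in enumerate(starts):
            try:
                popt, pcov = optimize.curve_fit(
                    self._func,
                    self.t,
                    self.y,
                    p0=np.clip(s, lo + 1e-8, hi - 1e-8),
                    bounds=(lo, hi),
                    maxfev=max_iter,
                    xtol=tol,
                    ftol=tol,
                    gtol=tol,
                )
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
            ssr = float(np.sum((self.y - self._func(self.t, *popt)) ** 2))
            if best is None or ssr < best[0] - 1e-12:
                best = (ssr, popt, pcov)
                used = i
        if best is None:
            nan = pd.Series(np.nan, index=self._names)
            return DecayResults(
                model=self.kind, params=nan, bse=nan.copy(),
                t=self.t, y=self.y, converged=False,
                df_resid=len(self.t) - self.n_params,
            )
        _, popt, pcov = best
        bse = np.sqrt(np.diag(pcov))
        return DecayResults(
            model=self.kind,
            params=pd.Series(popt, index=self._names),
            bse=pd.Series(bse, index=self._names),
            t=self.t,
            y=self.y,
            converged=bool(np.all(np.isfinite(popt)) and np.all(np.isfinite(bse))),
            n_restarts_used=used,
            df_resid=len(self.t) - self.n_params,
        )


def fit_decay(
    points: pd.DataFrame | tuple,
    model: str = "mono",
    start_values: Sequence[float] | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-10,
    *,
    seed: int = 0,
) -> DecayResults:
    """Functional wrapper: build a :class:`SoilCarbonDecayModel` and fit it."""
    if isinstance(points, pd.DataFrame):
        m = SoilCarbonDecayModel.from_points(points, kind=model)
    else:
        t, y = points
        m = SoilCarbonDecayModel(t, y, kind=model)
    return m.fit(start_values, max_iter=max_iter, tol=tol, seed=seed)


@dataclass
class ModelSelection:
    """Outcome of the mono-vs-bi choice with the reasons recorded."""

    chosen: DecayResults
    rationale: list[str] = field(default_factory=list)

    @property
    def model(self) -> str:
        return self.chosen.model


def select_model(
    fit_mono: DecayResults,
    fit_bi: DecayResults,
    *,
    alpha: float = 0.05,
    identity_threshold_pct: float = 0.5,
) -> ModelSelection:
    """Choose between the mono and bi fits on the same points.

    The mono model wins by parsimony when either (i) any bi decay rate is
    non-significant at ``alpha``, or (ii) the two fitted curves never differ by
    more than ``identity_threshold_pct`` percentage points over the observed
    ages. Otherwise the bi model is chosen.
    """
    if not fit_mono.converged and not fit_bi.converged:
        raise FitError("both decay fits failed; nothing to select")
    if not fit_bi.converged:
        return ModelSelection(fit_mono, ["bi fit did not converge"])
    if not fit_mono.converged:
        return ModelSelection(fit_bi, ["mono fit did not converge"])
    reasons = []
    bi_p = fit_bi.pvalues
    nonsig = [n for n in ("k1", "k2") if not (bi_p[n] <= alpha)]
    if nonsig:
        reasons.append(
            f"bi decay rate(s) {nonsig} non-significant at alpha={alpha}"
        )
    grid = np.linspace(float(fit_mono.t.min()), float(fit_mono.t.max()), 512)
    max_gap = float(np.max(np.abs(fit_mono.predict(grid) - fit_bi.predict(grid))))
    if max_gap <= identity_threshold_pct:
        reasons.append(
            f"fitted curves indistinguishable (max gap {max_gap:.3g} "
            f"<= {identity_threshold_pct} percentage points)"
        )
    if reasons:
        return ModelSelection(fit_mono, reasons)
    return ModelSelection(
        fit_bi, [f"bi rates significant and curves differ (max gap {max_gap:.3g})"]
    )
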
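"""Mixed-model land-use inference and the covariate correlation screen.

The paired-cluster design is analysed with a linear mixed-effects model:
fixed effects are land use, depth interval and their interaction; each cluster
gets a random intercept, absorbing the shared site conditions that the paired
sampling was designed to control. Rubber-minus-forest contrasts are tested per
depth interval (Wald tests) and the family of per-depth p-values for one
response is adjusted with Holm's step-down correction.

Residual variance is homoscedastic by default (statsmodels ``MixedLM``,
REML). When residual spread visibly differs between strata, a per-stratum
residual variance (by land use or by depth interval) can be requested; that
variant is fitted by a small REML routine written here, since ``MixedLM``
offers no unequal-variance residual structure.

The correlation screen uses Spearman rank correlations (mid-ranks for ties)
of carbon concentrations and of relative stock differences against site and
stand covariates, with exact permutation p-values at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LandUseMixedModel",
    "LandUseResults",
    "ContrastResult",
    "fit_landuse_model",
    "depth_contrasts",
    "holm_adjust",
    "significance_stars",
    "spearman_test",
    "spearman_screen",
    "CorrelationRow",
]


def significance_stars(p: float) -> str:
    """Conventional star codes; a dagger marks marginal significance (p <= 0.1)."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "†"
    return ""


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """One rubber-minus-forest contrast at one depth interval."""

    response: str
    interval: str
    estimate: float
    se: float
    p_raw: float
    p_holm: float = float("nan")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_holm)


def _design(data: pd.DataFrame, intervals: list[str]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design: intercept, rubber, depth dummies, interactions."""
    lu = (data["land_use"] == "rubber").to_numpy(dtype=float)
    cols = [np.ones(len(data)), lu]
    names = ["Intercept", "rubber"]
    for iv in intervals[1:]:
        d = (data["interval"] == iv).to_numpy(dtype=float)
        cols.append(d)
        names.append(f"depth[{iv}]")
    for iv in intervals[1:]:
        d = (data["interval"] == iv).to_numpy(dtype=float)
        cols.append(lu * d)
        names.append(f"rubber:depth[{iv}]")
    return np.column_stack(cols), names


class LandUseMixedModel:
    """Land use x depth mixed model with a cluster random intercept.

    Parameters
    ----------
    data : DataFrame
        Long table, one row per plot x depth interval, with columns
        ``cluster_id``, ``land_use`` ({"forest", "rubber"}), ``interval``
        (depth label) and the response column.
    response : str
        Name of the response column (a stock, a concentration, pH, ...).
    variance_by : {None, "land_use", "interval"}
        Optional per-stratum residual variances.
    """

    def __init__(self, data: pd.DataFrame, response: str, *, variance_by: str | None = None):
        required = {"cluster_id", "land_use", "interval", response}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"long table lacks column(s) {sorted(missing)}")
        data = data.dropna(subset=[response]).copy()
        if data["cluster_id"].nunique() < 2:
            raise ValueError(
                "a cluster random intercept needs >= 2 clusters; "
                "fit a fixed-effects model instead"
            )
        if set(data["land_use"].unique()) != {"forest", "rubber"}:
            raise ValueError("both land uses must be present")
        if variance_by not in (None, "land_use", "interval"):
            raise ValueError(f"variance_by must be None, 'land_use' or 'interval'")
        self.data = data
        self.response = response
        self.variance_by = variance_by
        def _depth_key(s):
            try:
                return (0, float(str(s).split("-")[0]))
            except ValueError:
                return (1, 0.0)

        self.intervals = sorted(data["interval"].unique(), key=_depth_key)
        self.exog, self.exog_names = _design(data, self.intervals)
        self.endog = data[response].to_numpy(dtype=float)
        self.groups = data["cluster_id"].to_numpy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kw):
        return cls(data, response, **kw)

    def fit(self) -> "LandUseResults":
        if self.variance_by is None:
            model = MixedLM(self.endog, self.exog, groups=self.groups)
            res = None
            # gradient-free fallbacks: the score can hit a singular iterate
            for method in ("lbfgs", "powell", "nm"):
                try:
                    res = model.fit(reml=True, method=method, maxiter=2000)
                    break
                except np.linalg.LinAlgError:
                    continue
            if res is None:
                raise RuntimeError("mixed-model optimisation failed for all methods")
            fe = pd.Series(res.fe_params, index=self.exog_names)
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            sig2 = float(res.scale)
            # degenerate data (e.g. a constant response) can drive the
            # variance estimates to 0/NaN; keep the GLS weights well posed
            floor = 1e-12 * (1.0 + float(np.var(self.endog)))
            if not np.isfinite(tau2) or tau2 < 0:
                tau2 = 0.0
            sig2 = sig2 if np.isfinite(sig2) and sig2 > floor else floor
            # Model-based GLS covariance of the fixed effects; well defined
            # even when the random-effect variance sits on the boundary.
            xtvx = np.zeros((self.exog.shape[1],) * 2)
            for cluster in pd.unique(self.groups):
                idx = np.flatnonzero(self.groups == cluster)
                Xc = self.exog[idx]
                Vc = np.full((len(idx), len(idx)), tau2)
                Vc[np.diag_indices(len(idx))] += sig2
                xtvx += Xc.T @ np.linalg.solve(Vc, Xc)
            cov = pd.DataFrame(
                np.linalg.inv(xtvx), index=self.exog_names, columns=self.exog_names
            )
            return LandUseResults(
                model=self,
                fe_params=fe,
                cov_fe=cov,
                cluster_var=tau2,
                resid_var={"all": sig2},
                converged=bool(res.converged),
                loglike=float(res.llf),
            )
        strata = self.data[self.variance_by].astype(str).to_numpy()
        return _fit_het_reml(self, strata)


@dataclass
class LandUseResults:
    """REML estimates of the land-use mixed model."""

    model: LandUseMixedModel
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    cluster_var: float
    resid_var: dict[str, float]
    converged: bool
    loglike: float

    def contrast(self, interval: str) -> tuple[float, float]:
        """(estimate, SE) of the rubber-minus-forest difference at a depth."""
        names = list(self.fe_params.index)
        if interval not in self.model.intervals:
            raise ValueError(f"interval {interval!r} not in the fitted model")
        L = np.zeros(len(names))
        L[names.index("rubber")] = 1.0
        inter = f"rubber:depth[{interval}]"
        if inter in names:
            L[names.index(inter)] = 1.0
        est = float(L @ self.fe_params.to_numpy())
        se = float(np.sqrt(L @ self.cov_fe.to_numpy() @ L))
        return est, se

    def contrasts(self, intervals: list[str] | None = None, *, holm: bool = True) -> list[ContrastResult]:
        """Per-depth rubber-minus-forest contrasts, Holm-adjusted as a family."""
        if intervals is None:
            intervals = self.model.intervals
        out = []
        for iv in intervals:
            est, se = self.contrast(iv)
            z = est / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            out.append(ContrastResult(self.model.response, iv, est, se, p))
        if holm:
            adj = holm_adjust([c.p_raw for c in out])
            for c, p in zip(out, adj):
                c.p_holm = float(p)
        else:
            for c in out:
                c.p_holm = c.p_raw
        return out

    def summary(self) -> str:
        lines = [
            f"Land-use mixed model for {self.model.response!r} "
            f"(REML, cluster random intercept)",
            f"n = {len(self.model.endog)} rows, "
            f"{self.model.data['cluster_id'].nunique()} clusters, "
            f"converged = {self.converged}",
            f"cluster variance = {self.cluster_var:.4g}; residual variance = "
            + ", ".join(f"{k}: {v:.4g}" for k, v in self.resid_var.items()),
            "",
            f"{'term':>24} {'estimate':>10} {'SE':>9}",
        ]
        se = np.sqrt(np.diag(self.cov_fe.to_numpy()))
        for name, est, s in zip(self.fe_params.index, self.fe_params, se):
            lines.append(f"{name:>24} {est:>10.4f} {s:>9.4f}")
        lines.append("")
        lines.append(f"{'contrast (rubber - forest)':>28} {'est':>9} {'SE':>8} {'p_holm':>8}")
        for c in self.contrasts():
            lines.append(
                f"{c.interval:>28} {c.estimate:>9.3f} {c.se:>8.3f} {c.p_holm:>8.3g} {c.stars}"
            )
        return "\n".join(lines)


def _fit_het_reml(model: LandUseMixedModel, strata: np.ndarray) -> LandUseResults:
    """REML for a cluster random intercept with per-stratum residual variances.

    Marginal covariance per cluster c: V_c = tau^2 J + diag(sigma^2_{g(i)}).
    beta is profiled out by GLS; the variance parameters are optimised on the
    log scale with Nelder-Mead.
    """
    y, X = model.endog, model.exog
    n, p = X.shape
    levels = sorted(set(strata))
    codes = np.array([levels.index(s) for s in strata])
    cluster_ids = pd.unique(model.groups)
    idx_by_cluster = [np.flatnonzero(model.groups == c) for c in cluster_ids]

    def reml_neg(theta):
        tau2 = math.exp(theta[0])
        sig2 = np.exp(theta[1:])
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        logdet = 0.0
        quads = []
        for idx in idx_by_cluster:
            Xc, yc = X[idx], y[idx]
            Vc = np.full((len(idx), len(idx)), tau2)
            Vc[np.diag_indices(len(idx))] += sig2[codes[idx]]
            sign, ld = np.linalg.slogdet(Vc)
            if sign <= 0:
                return 1e12
            logdet += ld
            Vinv = np.linalg.inv(Vc)
            xtvx += Xc.T @ Vinv @ Xc
            xtvy += Xc.T @ Vinv @ yc
            quads.append((Xc, yc, Vinv))
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return 1e12
        rss = 0.0
        for Xc, yc, Vinv in quads:
            r = yc - Xc @ beta
            rss += r @ Vinv @ r
        sign, ld_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return 1e12
        return 0.5 * (logdet + ld_xtvx + rss)

    var0 = float(np.var(y)) or 1.0
    theta0 = np.log(np.r_[0.3 * var0, np.full(len(levels), 0.7 * var0)])
    res = optimize.minimize(
        reml_neg, theta0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    theta = res.x
    tau2 = math.exp(theta[0])
    sig2 = np.exp(theta[1:])
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for idx in idx_by_cluster:
        Xc, yc = X[idx], y[idx]
        Vc = np.full((len(idx), len(idx)), tau2)
        Vc[np.diag_indices(len(idx))] += sig2[codes[idx]]
        Vinv = np.linalg.inv(Vc)
        xtvx += Xc.T @ Vinv @ Xc
        xtvy += Xc.T @ Vinv @ yc
    cov = np.linalg.inv(xtvx)
    beta = cov @ xtvy
    return LandUseResults(
        model=model,
        fe_params=pd.Series(beta, index=model.exog_names),
        cov_fe=pd.DataFrame(cov, index=model.exog_names, columns=model.exog_names),
        cluster_var=tau2,
        resid_var={lev: float(s) for lev, s in zip(levels, sig2)},
        converged=bool(res.success),
        loglike=-float(res.fun),
    )


def fit_landuse_model(
    data: pd.DataFrame, response: str, *, variance_by: str | None = None
) -> LandUseResults:
    """Functional wrapper around :class:`LandUseMixedModel`."""
    return LandUseMixedModel(data, response, variance_by=variance_by).fit()


def depth_contrasts(
    results: LandUseResults, intervals: list[str] | None = None
) -> list[ContrastResult]:
    """Per-depth rubber-minus-forest contrasts with Holm adjustment."""
    return results.contrasts(intervals, holm=True)


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationRow:
    """One cell of the correlation screen."""

    response: str
    covariate: str
    rho: float
    p_value: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


_EXACT_N_MAX = 9
_perm_cache: dict[int, np.ndarray] = {}


def _rank_perms(n: int) -> np.ndarray:
    if n not in _perm_cache:
        _perm_cache[n] = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    return _perm_cache[n]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    return float(x @ y) / denom if denom > 0 else float("nan")


def spearman_test(x, y) -> tuple[float, float, int]:
    """Spearman rho (mid-ranks) with a p-value; returns (rho, p, n).

    P-values: exact permutation distribution for n <= 9, the usual
    t-approximation otherwise. Pairs with missing values are dropped; if
    either variable is constant, rho is NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return float("nan"), float("nan"), n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson(rx, ry)
    if np.isnan(rho):
        return rho, float("nan"), n
    if n <= _EXACT_N_MAX:
        perms = _rank_perms(n)
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt(float(rxc @ rxc) * np.einsum("ij,ij->i", ryc, ryc))
        rhos = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        tstat = rho * math.sqrt((n - 2) / max(1 - rho * rho, 1e-300))
        p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return rho, p, n


def spearman_screen(
    responses: pd.DataFrame, covariates: pd.DataFrame
) -> list[CorrelationRow]:
    """All response x covariate Spearman tests on index-aligned frames.

    Both frames must share an index identifying the observational unit (plot
    or cluster, per the chosen pairing level); every column pair yields one
    :class:`CorrelationRow`. Cells with fewer than 3 complete cases or a
    constant column report NaN.
    """
    responses, covariates = responses.align(covariates, join="inner", axis=0)
    rows = []
    for resp in responses.columns:
        for cov in covariates.columns:
            rho, p, n = spearman_test(responses[resp], covariates[cov])
            rows.append(CorrelationRow(resp, cov, rho, p, n))
    return rows
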
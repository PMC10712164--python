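"""Growth-rate estimation, COD aggregation, phase stratification, and
correlation analysis of bioreactor time series.

The observed growth rate is the consecutive-pair log-slope of optical
density, assigned to interval midpoints, so each composition sample can
be paired with a time-resolved rate.  Organic substrates are aggregated
as chemical oxygen demand (COD, with 1 electron equivalent = 8 gCOD).
Relationships between rate, substrate, composition, and cell size are
summarized as Spearman correlograms at a 5% significance level and as
ordinary least-squares fits with pointwise 95% confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import COD_FACTORS, GCOD_PER_EEQ


class GrowthError(ValueError):
    """Raised for invalid time series or correlation inputs."""


# ---------------------------------------------------------------------------
# Rate and productivity estimators

def growth_rate(
    series: pd.DataFrame,
    od_col: str = "od600",
    time_col: str = "time_h",
    smooth: bool = False,
) -> pd.DataFrame:
    """Per-interval observed growth rate mu (1/h) from optical density.

    mu_i = ln(OD_{i+1}/OD_i) / (t_{i+1}-t_i), assigned to the interval
    midpoint.  With ``smooth`` a 3-point centered rolling mean is applied.
    Exact on pure exponentials for any sampling grid.
    """
    t = series[time_col].to_numpy(dtype=float)
    od = series[od_col].to_numpy(dtype=float)
    if len(t) < 2:
        raise GrowthError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise GrowthError("time must be strictly increasing")
    if np.any(od <= 0):
        raise GrowthError("non-positive OD values")
    mu = np.diff(np.log(od)) / np.diff(t)
    mid = (t[:-1] + t[1:]) / 2.0
    out = pd.DataFrame({"time_h": mid, "mu": mu})
    if smooth:
        out["mu"] = out["mu"].rolling(3, center=True, min_periods=1).mean()
    return out


def productivity(
    series: pd.DataFrame,
    cdw_col: str = "cdw_g_l",
    time_col: str = "time_h",
) -> pd.DataFrame:
    """Total cell productivity (g CDW / L / h) per interval, midpoint-assigned."""
    t = series[time_col].to_numpy(dtype=float)
    x = series[cdw_col].to_numpy(dtype=float)
    if len(t) < 2:
        raise GrowthError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise GrowthError("time must be strictly increasing")
    rate = np.diff(x) / np.diff(t)
    mid = (t[:-1] + t[1:]) / 2.0
    return pd.DataFrame({"time_h": mid, "productivity": rate})


def join_midpoints(
    series: pd.DataFrame,
    estimates: pd.DataFrame,
    time_col: str = "time_h",
    tol_h: float = 1.0,
) -> pd.DataFrame:
    """Attach midpoint-assigned estimates to the nearest sample time.

    Nearest-time match within ``tol_h`` hours (default 1 h, half the
    typical 2 h sampling interval); unmatched samples get NaN.
    """
    left = series.sort_values(time_col)
    right = estimates.sort_values(time_col)
    return pd.merge_asof(
        left,
        right,
        on=time_col,
        direction="nearest",
        tolerance=tol_h,
    )


# ---------------------------------------------------------------------------
# COD aggregation

def cod_aggregate(
    concentrations: Mapping[str, float],
    factors: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Aggregate organic compound concentrations (g/L) as COD and eeq.

    COD = sum_j c_j * f_j with f_j in gCOD/g from the built-in
    stoichiometric table (or a caller-supplied one); eeq = COD / 8.
    """
    factors = COD_FACTORS if factors is None else factors
    cod = 0.0
    for compound, conc in concentrations.items():
        if compound not in factors:
            raise GrowthError(f"no COD factor for compound {compound!r}")
        if conc < 0:
            raise GrowthError(f"negative concentration for {compound!r}")
        cod += conc * factors[compound]
    return cod, cod / GCOD_PER_EEQ


# ---------------------------------------------------------------------------
# Phase stratification

def classify_phase(
    series: pd.DataFrame,
    limitation: str,
    substrate_cols: Mapping[str, str] | None = None,
    frac_initial: float = 0.10,
    mu_frac: float = 0.90,
    mu_col: str = "mu",
) -> pd.Series:
    """Label each time point substrate-abundant or substrate-limiting.

    A point is "limiting" when the residual limiting substrate has fallen
    below ``frac_initial`` of its initial concentration AND the growth
    rate is below ``mu_frac`` of the run's maximum; otherwise "abundant".
    For dual limitation either substrate may trigger the rule.
    """
    substrate_cols = substrate_cols or {"carbon": "cod_g_l", "nitrogen": "nh4_g_l"}
    if limitation == "dual":
        which = list(substrate_cols)
    elif limitation in substrate_cols:
        which = [limitation]
    else:
        raise GrowthError(f"unknown limitation type {limitation!r}")
    if mu_col not in series:
        raise GrowthError(f"series lacks a {mu_col!r} column")
    mu = series[mu_col].to_numpy(dtype=float)
    mu_ok = mu < mu_frac * np.nanmax(mu)
    depleted = np.zeros(len(series), dtype=bool)
    for lim in which:
        col = substrate_cols[lim]
        s = series[col].to_numpy(dtype=float)
        depleted |= s <= frac_initial * s[0]
    labels = np.where(depleted & mu_ok, "limiting", "abundant")
    return pd.Series(labels, index=series.index, name="phase")


# ---------------------------------------------------------------------------
# Spearman correlograms

def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rank correlation with mid-rank ties and two-sided p.

    Pairwise-complete observations; p-value from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom.
    Returns (rho, p, n); rho is NaN when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise GrowthError("need at least 3 complete pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant variable; Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0, n
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p), n


@dataclass
class CorrelogramResult:
    """Pairwise Spearman correlations for one stratum of the data."""

    stratum: str
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    significant: pd.DataFrame
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        recs = []
        cols = list(self.rho.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                recs.append(
                    {
                        "stratum": self.stratum,
                        "var1": a,
                        "var2": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": self.n.loc[a, b],
                        "significant": bool(self.significant.loc[a, b]),
                    }
                )
        return pd.DataFrame.from_records(recs)


def correlogram(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    stratum: str = "all",
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> CorrelogramResult:
    """Pairwise Spearman correlogram over the given variables.

    Missing values are handled by pairwise-complete deletion.  No
    multiplicity correction by default (5% per-pair significance level);
    Benjamini-Hochberg across the upper triangle is available behind
    ``bh_correct``.
    """
    variables = list(variables) if variables is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    k = len(variables)
    if k < 2:
        raise GrowthError("need at least two variables")
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pmat = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    nmat = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    for v in variables:
        nmat.loc[v, v] = int(table[v].notna().sum())
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = variables[i], variables[j]
            r, p, n = spearman(table[a].to_numpy(), table[b].to_numpy())
            rho.loc[a, b] = rho.loc[b, a] = r
            pmat.loc[a, b] = pmat.loc[b, a] = p
            nmat.loc[a, b] = nmat.loc[b, a] = n
            pairs.append((a, b, p))
    if bh_correct:
        ps = np.array([p for _, _, p in pairs])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            idx = order[rank_idx]
            running = min(running, ps[idx] * m / (rank_idx + 1))
            adj[idx] = running
        for (a, b, _), q in zip(pairs, adj):
            pmat.loc[a, b] = pmat.loc[b, a] = q
    sig = (pmat < alpha) & rho.notna()
    np.fill_diagonal(sig.values, False)
    return CorrelogramResult(
        stratum=stratum, rho=rho, p=pmat, n=nmat, significant=sig, alpha=alpha
    )


def stratified_correlograms(
    table: pd.DataFrame,
    variables: Sequence[str],
    phase_col: str = "phase",
    limitation_col: str = "limitation",
    alpha: float = 0.05,
) -> dict[str, CorrelogramResult]:
    """Correlograms for {all, abundant, limiting} and per limitation type."""
    out = {"all": correlogram(table, variables, "all", alpha)}
    if phase_col in table:
        for phase in ("abundant", "limiting"):
            sub = table[table[phase_col] == phase]
            if len(sub) >= 3:
                out[phase] = correlogram(sub, variables, phase, alpha)
    if limitation_col in table:
        for lim, sub in table.groupby(limitation_col):
            if len(sub) >= 3:
                out[f"limitation:{lim}"] = correlogram(sub, variables, f"limitation:{lim}", alpha)
    return out


# ---------------------------------------------------------------------------
# Linear fits with confidence bands

@dataclass
class LinearFit:
    """OLS slope/intercept with a pointwise confidence band for the mean."""

    slope: float
    intercept: float
    x_grid: np.ndarray = field(repr=False)
    y_hat: np.ndarray = field(repr=False)
    ci_lo: np.ndarray = field(repr=False)
    ci_hi: np.ndarray = field(repr=False)
    level: float = 0.95


def linear_fit_ci(
    x: np.ndarray,
    y: np.ndarray,
    x_grid: np.ndarray | None = None,
    level: float = 0.95,
) -> LinearFit:
    """Ordinary least squares with the standard t-based pointwise CI.

    The band half-width at x0 is t_{1-a/2, n-2} * s * sqrt(1/n +
    (x0-xbar)^2 / Sxx), minimal at the mean of x; it has zero width when
    the data lie exactly on a line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise GrowthError("need at least 3 points")
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise GrowthError("zero variance in x")
    slope = float(((x - xbar) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    s2 = float((resid**2).sum() / (n - 2))
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 2)
    if x_grid is None:
        x_grid = np.linspace(x.min(), x.max(), 100)
    x_grid = np.asarray(x_grid, dtype=float)
    y_hat = intercept + slope * x_grid
    half = tcrit * np.sqrt(s2 * (1.0 / n + (x_grid - xbar) ** 2 / sxx))
    return LinearFit(
        slope=slope,
        intercept=intercept,
        x_grid=x_grid,
        y_hat=y_hat,
        ci_lo=y_hat - half,
        ci_hi=y_hat + half,
        level=level,
    )
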
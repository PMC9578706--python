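"""Enzyme-kinetics fitting and the surrounding two-sample statistics.

Covers the statistics layer of an in-vitro enzyme characterisation:

* Michaelis-Menten fits, v = Vmax*S/(Km+S), by nonlinear least squares
  with asymptotic t-based 95% confidence intervals (specific activity in
  micromoles of substrate transformed per minute per mg protein; S in mM);
* hyperbolic activator dose-response, v = vmax*A/(EC50+A), for the EC50 of
  an activator such as glucose-1,6-bisphosphate;
* a substrate-competition check comparing rates with and without a
  putative competing substrate;
* forward/reverse reaction-rate ratios (mean ± sample sd over replicates);
* Welch's unequal-variance t-test and the Mann-Whitney rank test in the
  first-sample U convention;
* quadratic least-squares regression with the overall-regression F test
  (used for hump-shaped fitness-vs-activity relationships);
* linear standard-curve calibration with inverse prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticsDataset",
    "KineticsFit",
    "QuadraticFit",
    "fit_mm",
    "fit_ec50",
    "competition_check",
    "forward_reverse_ratio",
    "welch_t",
    "mann_whitney",
    "fit_quadratic",
    "standard_curve_quantify",
]

#: Monomer molecular weight (Da) used to convert mg protein to mol enzyme
#: when computing kcat; conversion is always explicit, never implicit.
PGM1_MONOMER_DA = 63_000.0


@dataclass
class KineticsDataset:
    enzyme: str
    substrate_mM: Sequence[float]
    rate: Sequence[float]  # specific activity, U/mg
    temperature_C: float | None = None
    activator_uM: float | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.substrate_mM, dtype=float)
        if (S < 0).any():
            raise ValueError("substrate concentrations must be >= 0")
        if len(S) != len(self.rate):
            raise ValueError("substrate and rate must have equal length")


@dataclass
class KineticsFit:
    enzyme: str
    vmax: float
    vmax_ci95: float
    km: float
    km_ci95: float
    residual_sd: float
    n: int
    kcat_over_km: float | None = None  # 1/(s·mM), when molarity supplied
    warning: str | None = None


@dataclass
class QuadraticFit:
    b0: float
    b1: float
    b2: float
    r2: float
    r2_adj: float
    F: float
    df_model: int
    df_resid: int
    p: float


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def _hyperbolic_fit(x, y, label: str, x_name: str):
    """Shared core for MM and EC50 fits: v = vmax*x/(k + x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"{label}: need >= 4 points, got {n}")
    if len(np.unique(x)) < 2:
        raise ValueError(f"{label}: need >= 2 distinct {x_name} levels")
    if np.allclose(y, 0.0):
        raise ValueError(f"{label}: all rates are zero")
    vmax0 = float(y.max()) or 1.0
    half = vmax0 / 2
    above = x[y >= half]
    k0 = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
    if above.size:
        k0 = max(float(above.min()), np.finfo(float).tiny)
    try:
        # Unbounded Levenberg-Marquardt first (quadratic convergence near
        # the optimum); fall back to bounded trust-region if it wanders
        # into nonpositive parameters.
        popt, pcov = optimize.curve_fit(_mm, x, y, p0=[vmax0, k0], maxfev=10_000)
        if (popt <= 0).any():
            popt, pcov = optimize.curve_fit(
                _mm, x, y, p0=[vmax0, k0], maxfev=10_000, bounds=(0, np.inf)
            )
    except RuntimeError as exc:
        raise RuntimeError(f"{label}: fit did not converge ({exc})") from exc
    resid = y - _mm(x, *popt)
    dof = n - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    ci = tcrit * se
    warning = None
    if not (y > popt[0] / 2).any():
        warning = "no level exceeds half of the fitted maximum; k poorly constrained"
    return popt, ci, residual_sd, n, warning


def fit_mm(data: KineticsDataset, enzyme_mg_per_mol: float | None = None) -> KineticsFit:
    """Fit Michaelis-Menten parameters with asymptotic 95% CIs.

    CIs are t(0.975, n-2) times the asymptotic standard errors from the
    nonlinear least-squares covariance.  When ``enzyme_mg_per_mol`` (mg of
    protein per mol of enzyme, e.g. 63e6 for a 63 kDa monomer) is given,
    kcat/Km is reported in 1/(s*mM): kcat = Vmax[U/mg] * mg_per_mol / 60.
    """
    (vmax, km), (vmax_ci, km_ci), residual_sd, n, warning = _hyperbolic_fit(
        data.substrate_mM, data.rate, f"fit_mm[{data.enzyme}]", "substrate"
    )
    kcat_over_km = None
    if enzyme_mg_per_mol is not None:
        kcat = vmax * enzyme_mg_per_mol / 60.0  # U/mg = umol/min/mg -> 1/s
        kcat_over_km = float(kcat / km) * 1e-6  # umol->mol
    return KineticsFit(
        enzyme=data.enzyme,
        vmax=float(vmax),
        vmax_ci95=float(vmax_ci),
        km=float(km),
        km_ci95=float(km_ci),
        residual_sd=residual_sd,
        n=n,
        kcat_over_km=kcat_over_km,
        warning=warning,
    )


def fit_ec50(activator: Sequence[float], rate: Sequence[float], label: str = "EC50") -> dict:
    """Fit hyperbolic activation v = vmax*A/(EC50 + A).

    Returns {"ec50", "ec50_ci95", "vmax", "vmax_ci95", "residual_sd", "n",
    "warning"}.  Monotone-decreasing data (negative rate-vs-activator
    trend) is rejected: a decreasing response is not activation.
    """
    A = np.asarray(activator, dtype=float)
    y = np.asarray(rate, dtype=float)
    if len(A) >= 2 and np.polyfit(A, y, 1)[0] < 0:
        raise ValueError(f"{label}: rates decrease with activator; not an activation curve")
    (vmax, ec50), (vmax_ci, ec50_ci), residual_sd, n, warning = _hyperbolic_fit(
        A, y, label, "activator"
    )
    return {
        "ec50": float(ec50),
        "ec50_ci95": float(ec50_ci),
        "vmax": float(vmax),
        "vmax_ci95": float(vmax_ci),
        "residual_sd": residual_sd,
        "n": n,
        "warning": warning,
    }


def competition_check(
    control: KineticsDataset,
    with_competitor: dict[float, KineticsDataset],
) -> dict:
    """Compare rates with and without a putative competing substrate.

    ``with_competitor`` maps competitor concentration to a dataset measured
    on the same substrate grid as the control.  Returns per-concentration
    mean rate ratios vs control with normal-theory 95% CIs and a flag:
    "inhibition" when ratios are < 1 and strictly decrease with competitor
    concentration, "no inhibition" otherwise ("undefined" monotonicity for
    a single level with ratio ~1 keeps the no-inhibition flag).
    """
    S0 = np.asarray(control.substrate_mM, dtype=float)
    r0 = np.asarray(control.rate, dtype=float)
    concs = sorted(with_competitor)
    ratios = {}
    for c in concs:
        ds = with_competitor[c]
        S = np.asarray(ds.substrate_mM, dtype=float)
        if S.shape != S0.shape or not np.allclose(S, S0):
            raise ValueError(f"substrate grid at competitor {c} does not match control")
        rr = np.asarray(ds.rate, dtype=float) / r0
        n = len(rr)
        half = (
            float(stats.t.ppf(0.975, n - 1) * rr.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        )
        ratios[c] = {"mean_ratio": float(rr.mean()), "ci95_half_width": half}
    means = [ratios[c]["mean_ratio"] for c in concs]
    monotone_decreasing = len(means) >= 2 and all(b < a for a, b in zip(means, means[1:]))
    inhibited = monotone_decreasing and all(m < 1.0 for m in means)
    if len(means) == 1:
        flag = "inhibition" if means[0] < 0.9 else "no inhibition"
        monotonicity = "undefined"
    else:
        flag = "inhibition" if inhibited or all(m < 0.9 for m in means) else "no inhibition"
        monotonicity = "decreasing" if monotone_decreasing else "not decreasing"
    return {"ratios": ratios, "flag": flag, "monotonicity": monotonicity}


def forward_reverse_ratio(
    forward: Sequence[float], reverse: Sequence[float]
) -> tuple[float, float]:
    """Mean ± sample sd of per-replicate forward/reverse rate ratios.

    Replicates with a zero reverse rate are excluded with a warning.
    """
    f = np.asarray(list(forward), dtype=float)
    r = np.asarray(list(reverse), dtype=float)
    if len(f) != len(r):
        raise ValueError("forward and reverse must pair up")
    ok = r != 0
    if (~ok).any():
        warnings.warn(f"excluded {int((~ok).sum())} replicate(s) with zero reverse rate")
    f, r = f[ok], r[ok]
    if len(f) < 2:
        raise ValueError("need >= 2 usable replicate pairs")
    ratios = f / r
    return (float(ratios.mean()), float(ratios.std(ddof=1)))


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return (0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return (float(res.statistic), float(df), float(res.pvalue))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney rank test, first-sample U convention.

    W = #{(x_i, y_j): x_i > y_j} + half the ties.  The p-value is exact
    (full enumeration) when min(n, m) <= 8 and there are no ties, else a
    normal approximation with continuity and tie correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue))


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """Least-squares quadratic y = b0 + b1*x + b2*x^2 with ANOVA F test.

    The F statistic tests the overall regression (both slope terms zero)
    with (2, n-3) degrees of freedom.  Requires >= 4 points and at least
    three distinct x values (a quadratic through fewer is degenerate).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 points for a quadratic with a residual df")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")
    X = np.column_stack([np.ones(n), x, x**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = 2, n - 3
    if ss_tot == 0:
        r2, F, p = 0.0, 0.0, 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        ms_model = (ss_tot - ss_res) / df_model
        ms_resid = ss_res / df_resid
        if ms_resid == 0:
            F, p = float("inf"), 0.0
        else:
            F = ms_model / ms_resid
            p = float(stats.f.sf(F, df_model, df_resid))
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else float("nan")
    return QuadraticFit(
        b0=float(beta[0]),
        b1=float(beta[1]),
        b2=float(beta[2]),
        r2=r2,
        r2_adj=r2_adj,
        F=float(F),
        df_model=df_model,
        df_resid=df_resid,
        p=float(p),
    )


def standard_curve_quantify(
    standards: Sequence[tuple[float, float]],
    unknowns: Sequence[float] | Sequence[Sequence[float]],
) -> pd.DataFrame:
    """Quantify unknowns against a linear standard curve.

    ``standards`` are (concentration, signal) pairs; a least-squares line
    signal = a + b*conc is inverted for each unknown signal.  An unknown
    may be a single signal or a sequence of technical replicates, which
    are averaged before inversion.  Signals outside the standards' signal
    range are flagged as extrapolated.  Returns a DataFrame (signal,
    concentration, extrapolated).
    """
    st = np.asarray(list(standards), dtype=float)
    if st.shape[0] < 3:
        raise ValueError("need >= 3 standards")
    conc, sig = st[:, 0], st[:, 1]
    if np.ptp(sig) == 0:
        raise ValueError("standard curve has zero slope (constant signal)")
    b, a = np.polyfit(conc, sig, 1)
    if b == 0:
        raise ValueError("standard curve has zero slope")
    lo, hi = float(sig.min()), float(sig.max())
    rows = []
    for u in unknowns:
        s = float(np.mean(u)) if np.ndim(u) > 0 else float(u)
        rows.append(
            {
                "signal": s,
                "concentration": (s - a) / b,
                "extrapolated": bool(s < lo or s > hi),
            }
        )
    return pd.DataFrame(rows)
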
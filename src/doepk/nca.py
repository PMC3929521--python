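"""Non-compartmental pharmacokinetic analysis (NCA).

Given a plasma concentration-time profile, computes the standard model-free
summary: Cmax/tmax by direct maximum, terminal elimination rate lambda_z by
log-linear regression over a best-fit (maximal adjusted R^2) or user-fixed
terminal window, AUC and AUMC by the linear trapezoidal rule with tail
extrapolation Clast/lambda_z, half-life ln2/lambda_z and mean residence time
MRT = AUMC0-inf / AUC0-inf.  Group comparison uses Welch's unequal-variance
two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcTimeProfile",
    "NcaResult",
    "GroupComparison",
    "nca",
    "t_half",
    "welch_t_test",
    "summarize_group",
    "LambdaZError",
]


class LambdaZError(ValueError):
    """Terminal slope cannot be estimated (too few points or non-positive slope)."""


@dataclass
class ConcTimeProfile:
    """One subject's plasma concentration-time course.

    times in hours (strictly increasing, first >= 0); concentrations in
    ug/mL, >= 0.  Concentrations below ``loq`` after the first post-dose
    sample are treated as missing; a zero baseline at t = 0 is kept.
    """

    times: np.ndarray
    concentrations: np.ndarray
    subject: str = ""
    group: str = ""
    dose_mg_per_kg: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise ValueError("times and concentrations differ in length")
        if self.times.size == 0 or self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def quantified(self) -> tuple[np.ndarray, np.ndarray]:
        """Times/concentrations with sub-LOQ values dropped (post-baseline)."""
        t, c = self.times, self.concentrations
        if self.loq is None:
            return t, c
        keep = (c >= self.loq) | (np.arange(t.size) == 0)
        return t[keep], c[keep]


@dataclass
class NcaResult:
    """NCA parameter set for one profile."""

    cmax: float
    tmax: float
    lambda_z: float
    t_half: float
    auc_0_t: float
    auc_0_inf: float
    aumc_0_t: float
    aumc_0_inf: float
    mrt: float
    n_terminal_points: int
    adj_r_squared: float
    extrapolated_fraction: float
    subject: str = ""
    group: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def t_half(ke: float) -> float:
    """Elimination half-life ln(2)/ke (hours for ke in 1/h)."""
    if ke <= 0:
        raise ValueError("elimination rate constant must be positive")
    return float(np.log(2.0) / ke)


def _lambda_z_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Log-linear OLS of ln C on t; returns (lambda_z, adj R^2, intercept)."""
    logc = np.log(c)
    n = t.size
    slope, intercept, r, *_ = stats.linregress(t, logc)
    r2 = r**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return -slope, adj, intercept


def _terminal_window(
    t: np.ndarray, c: np.ndarray, tmax: float, rule
) -> tuple[np.ndarray, np.ndarray, float, float, int]:
    """Resolve the terminal window and fit lambda_z.

    rule='best-fit' evaluates every suffix of >= 3 positive-concentration
    points strictly after tmax and keeps the maximal adjusted R^2 (ties ->
    more points).  A (t_lo, t_hi) tuple fixes the window explicitly.
    """
    pos = c > 0
    if rule == "best-fit":
        candidates = np.where((t > tmax) & pos)[0]
        if candidates.size < 3:
            raise LambdaZError(
                "fewer than 3 positive terminal points after tmax"
            )
        best = None
        for start in range(candidates.size - 2):
            idx = candidates[start:]
            lz, adj, _ = _lambda_z_fit(t[idx], c[idx])
            if lz <= 0:
                continue
            if best is None or adj > best[1] + 1e-12:
                best = (lz, adj, idx)
        if best is None:
            raise LambdaZError("terminal slope non-positive in every window")
        lz, adj, idx = best
        return t[idx], c[idx], lz, adj, idx.size
    t_lo, t_hi = rule
    idx = np.where((t >= t_lo) & (t <= t_hi) & pos)[0]
    if idx.size < 3:
        raise LambdaZError("fewer than 3 positive points in the fixed window")
    lz, adj, _ = _lambda_z_fit(t[idx], c[idx])
    if lz <= 0:
        raise LambdaZError("terminal slope is non-positive")
    return t[idx], c[idx], lz, adj, idx.size


def nca(profile: ConcTimeProfile, terminal_rule="best-fit") -> NcaResult:
    """Full non-compartmental analysis of one profile.

    ``terminal_rule`` is ``'best-fit'`` (default) or an explicit
    ``(t_lo, t_hi)`` window in hours.
    """
    t, c = profile.quantified()
    if np.count_nonzero(c > 0) < 3:
        raise LambdaZError("need >= 3 positive concentrations")

    imax = int(np.argmax(c))  # argmax returns the earliest maximum on ties
    cmax, tmax = float(c[imax]), float(t[imax])

    _, _, lz, adj, n_term = _terminal_window(t, c, tmax, terminal_rule)

    auc_0_t = float(np.trapezoid(c, t))
    aumc_0_t = float(np.trapezoid(t * c, t))
    clast, tlast = float(c[-1]), float(t[-1])
    auc_inf = auc_0_t + clast / lz
    aumc_inf = aumc_0_t + clast * tlast / lz + clast / lz**2

    return NcaResult(
        cmax=cmax,
        tmax=tmax,
        lambda_z=lz,
        t_half=t_half(lz),
        auc_0_t=auc_0_t,
        auc_0_inf=auc_inf,
        aumc_0_t=aumc_0_t,
        aumc_0_inf=aumc_inf,
        mrt=aumc_inf / auc_inf,
        n_terminal_points=n_term,
        adj_r_squared=adj,
        extrapolated_fraction=(auc_inf - auc_0_t) / auc_inf,
        subject=profile.subject,
        group=profile.group,
    )


@dataclass
class GroupComparison:
    """Welch two-sample comparison of one PK parameter between groups."""

    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    df: float
    p_value: float


def welch_t_test(values_a, values_b, parameter: str = "") -> GroupComparison:
    """Two-tailed unpaired t test with Welch's correction.

    t = (ma - mb) / sqrt(sa^2/na + sb^2/nb) with Welch-Satterthwaite degrees
    of freedom; when both groups are constant and equal, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
    if sa2 == 0 and sb2 == 0:
        tstat, p = 0.0, 1.0
        dfw = float(a.size + b.size - 2)
        if a.mean() != b.mean():
            tstat, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        tstat, p = float(res.statistic), float(res.pvalue)
        dfw = float(res.df)
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_statistic=tstat,
        df=dfw,
        p_value=p,
    )


def summarize_group(results: list[NcaResult]) -> pd.DataFrame:
    """Mean +- SD per NCA parameter over a cohort (sample SD, n-1)."""
    if len(results) < 2:
        raise ValueError("need >= 2 subjects to summarize")
    numeric = [
        "cmax", "tmax", "lambda_z", "t_half",
        "auc_0_t", "auc_0_inf", "aumc_0_t", "aumc_0_inf", "mrt",
    ]
    frame = pd.DataFrame([r.to_dict() for r in results])[numeric]
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})
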
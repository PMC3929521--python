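"""Analytical method validation statistics for HPLC assays.

Implements the ICH-style validation battery: calibration linearity by least
squares (:class:`CalibrationCurve`), detection/quantitation limits from the
3.3*sigma/S and 10*sigma/S rules, precision as percent relative standard
deviation, accuracy as the observed/nominal ratio, bioanalytical 15%/20%
acceptance checks, and chromatographic system-suitability metrics (capacity
factor, plate number, tailing factor, resolution) from peak descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationCurve",
    "QcReplicateSet",
    "PeakRecord",
    "ValidationReport",
    "fit_calibration",
    "lod_loq",
    "precision_rsd",
    "accuracy_pct",
    "acceptance_check",
    "system_suitability",
    "stability_accuracy",
]


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Least-squares calibration line: signal = slope * concentration + intercept.

    Parameters
    ----------
    weighting : {None, "1/x", "1/x2"}
        Optional weighted least squares with weights 1/conc or 1/conc**2.
        Unweighted OLS is the default.

    Attributes
    ----------
    slope_ : float
        Calibration sensitivity S, signal units per concentration unit.
    intercept_ : float
    r_squared_ : float
        Squared Pearson correlation of fitted vs observed signal.
    resid_std_ : float
        Residual standard deviation of the regression (sigma for LOD/LOQ).
    response_factors_ : ndarray
        Per-point signal/concentration ratios.
    """

    def __init__(self, weighting: str | None = None):
        self.weighting = weighting

    def fit(self, concentrations, signals) -> "CalibrationCurve":
        x = np.asarray(concentrations, dtype=float).ravel()
        y = np.asarray(signals, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("concentrations and signals differ in length")
        if np.unique(x).size < 2:
            raise ValueError("degenerate design: all concentrations identical")
        if self.weighting is None:
            w = np.ones_like(x)
        elif self.weighting == "1/x":
            w = 1.0 / x
        elif self.weighting == "1/x2":
            w = 1.0 / x**2
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        yhat = res.fittedvalues
        if np.allclose(yhat, yhat[0]) or np.allclose(y, y[0]):
            self.r_squared_ = 1.0 if np.allclose(y, yhat) else 0.0
        else:
            self.r_squared_ = float(np.corrcoef(y, yhat)[0, 1] ** 2)
        self.resid_std_ = (
            float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            self.response_factors_ = np.where(x != 0, y / x, np.nan)
        self.n_points_ = int(x.size)
        return self

    def predict(self, concentrations) -> np.ndarray:
        check_is_fitted(self, "slope_")
        x = np.asarray(concentrations, dtype=float)
        return self.slope_ * x + self.intercept_

    def inverse(self, signals) -> np.ndarray:
        """Back-calculate concentration from signal."""
        check_is_fitted(self, "slope_")
        return (np.asarray(signals, dtype=float) - self.intercept_) / self.slope_


def fit_calibration(
    concentrations, signals, weighting: str | None = None
) -> CalibrationCurve:
    """Fit a calibration line by (weighted) least squares.

    Guideline practice uses >= 3 distinct concentration levels; two distinct
    points give the exact interpolating line (R^2 = 1), and identical
    concentrations everywhere raise a degenerate-design error.
    """
    return CalibrationCurve(weighting=weighting).fit(concentrations, signals)


def lod_loq(sigma: float, slope: float) -> tuple[float, float]:
    """Limits of detection and quantitation: LOD = 3.3*sigma/S, LOQ = 10*sigma/S.

    ``sigma`` is the standard deviation of the response (by default the
    residual SD of a low-concentration calibration line) and ``S`` the
    calibration slope.  The LOQ/LOD ratio is 10/3.3 by construction.
    """
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 3.3 * sigma / slope, 10.0 * sigma / slope


@dataclass(frozen=True)
class QcReplicateSet:
    """Replicate QC determinations at one nominal concentration."""

    nominal: float
    observed: tuple[float, ...]
    session: str = ""

    def __post_init__(self) -> None:
        if len(self.observed) < 2:
            raise ValueError("need >= 2 replicates")
        if any(v <= 0 for v in self.observed):
            raise ValueError("observed concentrations must be positive")


def precision_rsd(values) -> float:
    """Percent relative standard deviation, 100 * SD / mean (sample SD, n-1)."""
    v = np.asarray(
        values.observed if isinstance(values, QcReplicateSet) else values,
        dtype=float,
    )
    if v.size < 2:
        raise ValueError("need >= 2 replicates")
    m = v.mean()
    if m == 0:
        raise ValueError("mean of replicates is zero")
    return float(100.0 * v.std(ddof=1) / m)


def accuracy_pct(observed_mean: float, nominal: float) -> float:
    """Percent accuracy = 100 * observed / nominal."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return 100.0 * observed_mean / nominal


def stability_accuracy(measured: float, spiked: float) -> float:
    """Stability expressed as percent accuracy of the measured vs spiked level."""
    return accuracy_pct(measured, spiked)


def acceptance_check(level: QcReplicateSet, is_lloq: bool = False) -> dict:
    """Bioanalytical acceptance: RSD and |bias| within 15% (20% at the LLOQ).

    Returns a dict with the computed %RSD, %accuracy, threshold, a ``passed``
    flag and human-readable ``reasons`` for any failure.
    """
    threshold = 20.0 if is_lloq else 15.0
    rsd = precision_rsd(level)
    acc = accuracy_pct(float(np.mean(level.observed)), level.nominal)
    reasons = []
    if rsd > threshold:
        reasons.append(f"%RSD {rsd:.2f} exceeds {threshold:.0f}%")
    if abs(100.0 - acc) > threshold:
        reasons.append(f"bias {abs(100.0 - acc):.2f}% exceeds {threshold:.0f}%")
    return {
        "nominal": level.nominal,
        "session": level.session,
        "rsd_pct": rsd,
        "accuracy_pct": acc,
        "threshold_pct": threshold,
        "passed": not reasons,
        "reasons": reasons,
    }


@dataclass(frozen=True)
class PeakRecord:
    """Geometric descriptors of one chromatographic peak.

    All times/widths in minutes: retention time ``tr``, width at base ``w``,
    width at 5% height ``w05``, leading (front) half-width at 5% height
    ``f``, width at half height ``w_half``, and column void time ``t0``.
    """

    tr: float
    w: float
    w05: float
    f: float
    w_half: float
    t0: float

    def __post_init__(self) -> None:
        for name in ("tr", "w", "w05", "f", "w_half", "t0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f > self.w05 + 1e-12:
            raise ValueError("front half-width f cannot exceed w05")


def system_suitability(
    peak: PeakRecord, reference_peak: PeakRecord | None = None
) -> dict:
    """System-suitability metrics from peak descriptors.

    capacity factor     k' = (tr - t0) / t0
    plate number        N  = 16 (tr/w)^2  (base width) and
                        N  = 5.54 (tr/w_half)^2  (half height) — both reported
    tailing factor      T  = w05 / (2 f)  (USP, 5% height)
    resolution          Rs = 2 (tr2 - tr1) / (w1 + w2)  vs the reference peak

    Rs is omitted (not an error) when no reference peak is given.
    """
    out = {
        "k_prime": (peak.tr - peak.t0) / peak.t0,
        "plates_base": 16.0 * (peak.tr / peak.w) ** 2,
        "plates_half_height": 5.54 * (peak.tr / peak.w_half) ** 2,
        "tailing_factor": peak.w05 / (2.0 * peak.f),
    }
    if reference_peak is not None:
        out["resolution"] = (
            2.0 * abs(peak.tr - reference_peak.tr) / (peak.w + reference_peak.w)
        )
    return out


@dataclass
class ValidationReport:
    """Aggregate validation summary: calibration, limits, QC levels, peaks."""

    calibration: dict
    lod: float
    loq: float
    qc_levels: list[dict]
    suitability: list[dict]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = ["Method validation report", "========================"]
        cal = self.calibration
        lines.append(
            f"Calibration: slope {cal['slope']:.4g}, intercept "
            f"{cal['intercept']:.4g}, R^2 {cal['r_squared']:.5f} "
            f"({cal['n_points']} points)"
        )
        lines.append(f"LOD {self.lod:.4g}, LOQ {self.loq:.4g} (conc. units)")
        for q in self.qc_levels:
            status = "PASS" if q["passed"] else "FAIL: " + "; ".join(q["reasons"])
            lines.append(
                f"QC {q['nominal']:g} ({q['session'] or 'n/a'}): "
                f"RSD {q['rsd_pct']:.2f}%, accuracy {q['accuracy_pct']:.2f}% "
                f"[{status}]"
            )
        for i, s in enumerate(self.suitability, 1):
            rs = f", Rs {s['resolution']:.2f}" if "resolution" in s else ""
            lines.append(
                f"Peak {i}: k' {s['k_prime']:.2f}, N {s['plates_half_height']:.0f}"
                f" (half-height), T {s['tailing_factor']:.2f}{rs}"
            )
        return "\n".join(lines)


def build_validation_report(
    curve: CalibrationCurve,
    qc_sets: list[QcReplicateSet],
    peaks: list[tuple[PeakRecord, PeakRecord | None]] | None = None,
    lloq_nominal: float | None = None,
    sigma: float | None = None,
) -> ValidationReport:
    """Assemble a :class:`ValidationReport` from fitted pieces.

    ``sigma`` defaults to the calibration residual SD; ``lloq_nominal`` marks
    which QC level is the lower limit of quantitation (wider 20% acceptance).
    """
    check_is_fitted(curve, "slope_")
    sig = curve.resid_std_ if sigma is None else sigma
    lod, loq = lod_loq(sig, curve.slope_)
    qc = [
        acceptance_check(
            s, is_lloq=(lloq_nominal is not None and s.nominal == lloq_nominal)
        )
        for s in qc_sets
    ]
    suit = [system_suitability(p, ref) for p, ref in (peaks or [])]
    return ValidationReport(
        calibration={
            "slope": curve.slope_,
            "intercept": curve.intercept_,
            "r_squared": curve.r_squared_,
            "resid_std": curve.resid_std_,
            "n_points": curve.n_points_,
        },
        lod=lod,
        loq=loq,
        qc_levels=qc,
        suitability=suit,
    )
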
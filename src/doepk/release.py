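"""Nanoparticle encapsulation metrics and in-vitro drug-release kinetics.

Encapsulation efficiency and drug loading are simple mass-balance ratios on a
formulation batch.  Release profiles sampled with aliquot replacement (take
``Va`` mL, replace with fresh medium) underestimate cumulative release unless
the withdrawn drug is added back; :func:`cumulative_release` applies the
standard additive correction

    Cn_corr = Cn + (Va / Vm) * sum_{i<n} Ci

before converting released mass to percent of dose.  Release curves are then
fitted with :class:`ReleaseKinetics` to the zero-order, first-order or
Higuchi model via the linearizing transform of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FormulationBatch",
    "ReleaseProfile",
    "ReleaseKinetics",
    "encapsulation_efficiency",
    "drug_loading",
    "cumulative_release",
    "fit_release_model",
]


@dataclass(frozen=True)
class FormulationBatch:
    """Mass balance of one nanoparticle preparation (all masses in mg)."""

    drug_added: float
    free_drug: float
    drug_in_nps: float = 0.0
    np_weight: float = 0.0

    def __post_init__(self) -> None:
        for name in ("drug_added", "free_drug", "drug_in_nps", "np_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.free_drug > self.drug_added:
            raise ValueError(
                "mass-balance error: free drug exceeds drug added"
            )


def encapsulation_efficiency(batch: FormulationBatch) -> float:
    """Percent of added drug retained in the particles.

    EE% = 100 * (drug added - free drug in supernatant) / drug added.
    """
    if batch.drug_added <= 0:
        raise ValueError("drug_added must be positive")
    return 100.0 * (batch.drug_added - batch.free_drug) / batch.drug_added


def drug_loading(batch: FormulationBatch) -> float:
    """Percent drug content of the recovered particles.

    DL% = 100 * drug in nanoparticles / nanoparticle weight recovered.
    """
    if batch.np_weight <= 0:
        raise ValueError("nanoparticle weight must be positive")
    return 100.0 * batch.drug_in_nps / batch.np_weight


@dataclass
class ReleaseProfile:
    """A sampled release study.

    ``times`` strictly increasing, first >= 0, in the declared ``time_unit``.
    ``concentrations`` are aliquot concentrations (ug/mL) when the profile
    carries raw samples, or ``cumulative_pct`` when already converted.
    ``medium_volume``/``aliquot_volume`` in mL; ``dose_mg`` is the drug mass
    in the device.
    """

    times: np.ndarray
    concentrations: np.ndarray | None = None
    cumulative_pct: np.ndarray | None = None
    medium_volume: float = 200.0
    aliquot_volume: float = 1.0
    dose_mg: float = 200.0
    time_unit: str = "day"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0 or self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.concentrations is not None:
            self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.cumulative_pct is not None:
            self.cumulative_pct = np.asarray(self.cumulative_pct, dtype=float)
        if self.medium_volume <= 0 or self.aliquot_volume < 0:
            raise ValueError("volumes must be positive (aliquot may be 0)")
        if self.aliquot_volume >= self.medium_volume:
            raise ValueError("aliquot must be smaller than the medium volume")


def cumulative_release(profile: ReleaseProfile, tolerance: float = 1.0) -> np.ndarray:
    """Sampling-corrected cumulative percent released at each time point.

    Applies the additive aliquot-replacement correction to the measured
    concentrations, converts corrected concentration to released mass
    (``C_corr * Vm``) and scales by the dose.  With ``aliquot_volume = 0``
    this reduces to naive concentration-to-percent scaling.  Values above
    ``100 + tolerance`` set a mass-balance warning on the profile instead of
    raising.
    """
    if profile.concentrations is None:
        if profile.cumulative_pct is None:
            raise ValueError("profile carries neither concentrations nor percentages")
        return profile.cumulative_pct
    c = profile.concentrations
    va, vm = profile.aliquot_volume, profile.medium_volume
    csum = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    c_corr = c + (va / vm) * csum
    released_ug = c_corr * vm  # ug/mL * mL
    pct = 100.0 * released_ug / (profile.dose_mg * 1000.0)
    if np.any(pct > 100.0 + tolerance):
        profile.warnings.append(
            f"mass balance: corrected release peaks at {pct.max():.1f}% > 100%"
        )
    profile.cumulative_pct = pct
    return pct


_MODELS = ("zero", "first", "higuchi")


class ReleaseKinetics(BaseEstimator, RegressorMixin):
    """Release-model fit on the linearizing transform of the chosen model.

    model='zero':    Q = k*t + intercept          (k in %/time)
    model='first':   ln(100 - Q) = ln(100-b) - k*t (k in 1/time)
    model='higuchi': Q = k*sqrt(t) + intercept     (k in %/sqrt(time))

    ``through_origin=True`` forces the zero/higuchi intercept (burst term)
    to zero.  Points where the transform is non-finite (e.g. Q >= 100 under
    the first-order model) are excluded with a recorded warning.

    Attributes
    ----------
    rate_ : float
        Rate constant k of the chosen model.
    intercept_ : float
        Burst intercept on the transformed scale mapped back to percent.
    r_squared_ : float
        R^2 of the linearized regression.
    """

    def __init__(self, model: str = "zero", through_origin: bool = False):
        self.model = model
        self.through_origin = through_origin

    def fit(self, times, cumulative_pct) -> "ReleaseKinetics":
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        t = np.asarray(times, dtype=float).ravel()
        q = np.asarray(cumulative_pct, dtype=float).ravel()
        if t.size != q.size:
            raise ValueError("times and release values differ in length")
        if t.size < 3:
            raise ValueError("need >= 3 points to fit a release model")
        self.warnings_ = []

        if self.model == "zero":
            x, y = t, q
        elif self.model == "higuchi":
            x, y = np.sqrt(t), q
        else:  # first order
            remaining = 100.0 - q
            ok = remaining > 0
            if not ok.all():
                self.warnings_.append(
                    f"excluded {int((~ok).sum())} point(s) with Q >= 100% "
                    "from the first-order transform"
                )
            t, q = t[ok], q[ok]
            if t.size < 3:
                raise ValueError("fewer than 3 finite points after transform")
            x, y = t, np.log(100.0 - q)

        if self.through_origin and self.model in ("zero", "higuchi"):
            slope = float(np.dot(x, y) / np.dot(x, x))
            intercept = 0.0
            yhat = slope * x
        else:
            slope, intercept = np.polyfit(x, y, 1)
            yhat = slope * x + intercept
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum((y - yhat) ** 2))
        self.r_squared_ = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

        if self.model == "first":
            self.rate_ = float(-slope)
            self.intercept_ = float(100.0 - np.exp(intercept))
        else:
            self.rate_ = float(slope)
            self.intercept_ = float(intercept)
        self.n_points_ = int(x.size)
        return self

    def predict(self, times) -> np.ndarray:
        check_is_fitted(self, "rate_")
        t = np.asarray(times, dtype=float)
        if self.model == "zero":
            return self.rate_ * t + self.intercept_
        if self.model == "higuchi":
            return self.rate_ * np.sqrt(t) + self.intercept_
        return 100.0 - (100.0 - self.intercept_) * np.exp(-self.rate_ * t)


def fit_release_model(
    profile: ReleaseProfile | None = None,
    model: str = "zero",
    times=None,
    cumulative_pct=None,
    through_origin: bool = False,
) -> ReleaseKinetics:
    """Fit one kinetic model to a release profile (or raw arrays)."""
    if profile is not None:
        times = profile.times
        cumulative_pct = (
            profile.cumulative_pct
            if profile.cumulative_pct is not None
            else cumulative_release(profile)
        )
    return ReleaseKinetics(model=model, through_origin=through_origin).fit(
        times, cumulative_pct
    )
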
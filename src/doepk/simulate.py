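"""Synthetic data generators with known ground truth.

Every input class the analysis modules consume can be generated here under a
fixed seed, enabling closed-loop recovery tests: quadratic response surfaces
with Gaussian noise over a design, one-compartment oral-absorption plasma
profiles with log-normal noise, burst + zero-order release curves, Gaussian /
exponentially-modified-Gaussian chromatographic peaks, and linear calibration
curves.  Each generator returns ``(data, truth)`` where ``truth`` records the
generating parameters.

Noise models: additive Gaussian for surfaces, calibration signals and release
percentages; multiplicative log-normal (median 1) for plasma concentrations,
which keeps them non-negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .nca import ConcTimeProfile
from .release import ReleaseProfile
from .rsm import quadratic_term_names, _design_matrix
from .validation import PeakRecord

__all__ = [
    "simulate_rsm_dataset",
    "simulate_oral_pk",
    "simulate_release",
    "simulate_chromatogram",
    "simulate_calibration",
    "oral_concentration",
    "PK_SAMPLING_SCHEDULE_H",
    "CALIBRATION_LEVELS_UG_ML",
]

# Dense early sampling then daily draws out to 10 days.
PK_SAMPLING_SCHEDULE_H = np.array(
    [0.0, 1, 2, 4, 6, 8, 12] + list(range(24, 241, 24)), dtype=float
)

# Eight-point calibration schedule in ug/mL.
CALIBRATION_LEVELS_UG_ML = np.array([0.040, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0])


def simulate_rsm_dataset(
    coefficients,
    design: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int | None = None,
    response_name: str = "y",
) -> tuple[pd.DataFrame, dict]:
    """Responses from a known quadratic surface evaluated on a design table.

    ``coefficients`` are ordered as :func:`doepk.rsm.quadratic_term_names`
    (intercept, linear, interactions i<j, quadratics).  Gaussian noise with
    SD ``noise_sd`` is added i.i.d. per run; zero noise returns the exact
    surface.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    factor_cols = [
        c for c in design.columns if c not in ("exp_no", "run_order", "point_type")
    ]
    X = design[factor_cols].to_numpy(dtype=float)
    k = X.shape[1]
    beta = np.asarray(coefficients, dtype=float)
    names = quadratic_term_names(k)
    if beta.size != len(names):
        raise ValueError(
            f"need {len(names)} coefficients for {k} factors, got {beta.size}"
        )
    y = _design_matrix(X) @ beta
    rng = np.random.default_rng(seed)
    y = y + rng.normal(0.0, noise_sd, size=y.shape) if noise_sd > 0 else y
    table = pd.DataFrame({response_name: y})
    truth = {
        "coefficients": dict(zip(names, beta)),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return table, truth


def oral_concentration(
    t, ka: float, ke: float, v_over_f: float, dose_mg: float
) -> np.ndarray:
    """One-compartment first-order absorption concentration (ug/mL).

    C(t) = dose*ka / (V/F * (ka - ke)) * (exp(-ke t) - exp(-ka t)),
    with dose in mg and V/F in L so dose/V is mg/L = ug/mL.
    """
    if ka <= 0 or ke <= 0:
        raise ValueError("ka and ke must be positive")
    if ka == ke:
        raise ValueError("flip-flop degenerate case ka == ke is not supported")
    t = np.asarray(t, dtype=float)
    return (
        dose_mg * ka / (v_over_f * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    )


def simulate_oral_pk(
    ka: float = 1.5,
    ke: float = 0.07,
    v_over_f: float = 1.0,
    dose_mg: float = 4.0,
    times=None,
    noise_cv: float = 0.0,
    seed: int | None = None,
    n_subjects: int = 6,
    group: str = "free drug",
) -> tuple[list[ConcTimeProfile], dict]:
    """Cohort of one-compartment oral-absorption plasma profiles.

    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` and median 1, so zero CV gives identical noise-free
    subjects.  Defaults mimic a rapidly absorbed drug (ka = 1.5/h) with a
    ~10 h half-life (ke = 0.07/h) sampled on the dense-early/daily-late
    schedule.
    """
    if times is None:
        times = PK_SAMPLING_SCHEDULE_H
    times = np.asarray(times, dtype=float)
    clean = oral_concentration(times, ka, ke, v_over_f, dose_mg)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    profiles = []
    for i in range(n_subjects):
        if noise_cv > 0:
            noise = np.exp(rng.normal(0.0, sigma, size=times.shape))
            conc = clean * noise
        else:
            conc = clean.copy()
        conc[times == 0.0] = 0.0  # pre-dose baseline
        profiles.append(
            ConcTimeProfile(
                times=times,
                concentrations=conc,
                subject=f"S{i + 1}",
                group=group,
            )
        )
    tmax = np.log(ka / ke) / (ka - ke)
    truth = {
        "ka": ka,
        "ke": ke,
        "v_over_f": v_over_f,
        "dose_mg": dose_mg,
        "tmax_analytic": tmax,
        "cmax_analytic": float(
            oral_concentration(np.array([tmax]), ka, ke, v_over_f, dose_mg)[0]
        ),
        "auc_inf_analytic": dose_mg / (v_over_f * ke),
        "noise_cv": noise_cv,
        "seed": seed,
    }
    return profiles, truth


# Burst rate constant (1/day): fast enough that the burst is complete within
# the first day and visually distinct from the zero-order phase.
BURST_RATE_PER_DAY = 5.0


def simulate_release(
    burst_pct: float = 10.4,
    k0: float = 4.64,
    times=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dose_mg: float = 200.0,
) -> tuple[ReleaseProfile, dict]:
    """Burst + zero-order cumulative release curve.

    Q(t) = burst_pct * (1 - exp(-5 t)) + k0 * t (+ Gaussian noise), capped at
    100%.  Default parameters give ~15% cumulative release at day 1 and ~80%
    at day 15, the sustained-release pattern the package models.
    """
    if times is None:
        times = np.arange(0.0, 15.5, 0.5)
    times = np.asarray(times, dtype=float)
    if burst_pct < 0 or k0 < 0 or noise_sd < 0:
        raise ValueError("burst, k0 and noise must be >= 0")
    if burst_pct + k0 * times.max() > 100.0:
        raise ValueError("parameters imply > 100% release at the last time point")
    q = burst_pct * (1.0 - np.exp(-BURST_RATE_PER_DAY * times)) + k0 * times
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=q.shape)
    q = np.clip(q, 0.0, 100.0)
    profile = ReleaseProfile(
        times=times, cumulative_pct=q, dose_mg=dose_mg, time_unit="day"
    )
    truth = {
        "burst_pct": burst_pct,
        "k0": k0,
        "burst_rate": BURST_RATE_PER_DAY,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return profile, truth


def _emg_pdf(t, mu, sigma, tau):
    if tau <= 0:
        return stats.norm.pdf(t, loc=mu, scale=sigma)
    return stats.exponnorm.pdf(t, tau / sigma, loc=mu, scale=sigma)


def _crossing(func, level, lo, hi):
    return optimize.brentq(lambda t: func(t) - level, lo, hi, xtol=1e-10)


def _peak_record(tr_mode, mu, sigma, tau, t0) -> PeakRecord:
    """Widths of the analytic (E)MG shape at 50%, 5% and ~0.1% of peak height."""
    f_ = lambda t: _emg_pdf(t, mu, sigma, tau)
    peak_h = f_(tr_mode)
    left0 = mu - 8 * sigma
    right0 = tr_mode + 8 * sigma + 12 * tau
    widths = {}
    for frac in (0.5, 0.05, 0.001):
        lo = _crossing(f_, frac * peak_h, left0, tr_mode)
        hi = _crossing(f_, frac * peak_h, tr_mode, right0)
        widths[frac] = (lo, hi)
    w_half = widths[0.5][1] - widths[0.5][0]
    w05 = widths[0.05][1] - widths[0.05][0]
    f_lead = tr_mode - widths[0.05][0]
    w_base = widths[0.001][1] - widths[0.001][0]  # tangent-free base proxy
    if tau == 0:
        w_base = 4.0 * sigma  # Gaussian convention: base width = 4 sigma
    return PeakRecord(
        tr=tr_mode, w=w_base, w05=w05, f=f_lead, w_half=w_half, t0=t0
    )


def simulate_chromatogram(
    peaks: list[dict],
    baseline_noise: float = 0.0,
    seed: int | None = None,
    t0: float = 0.9,
    sample_rate_hz: float = 5.0,
) -> tuple[pd.DataFrame, list[PeakRecord], dict]:
    """Sampled chromatogram trace plus analytic peak descriptors.

    Each peak spec is ``{"tr": min, "height": au, "sigma": min, "tau": min}``
    where ``tau`` is the exponential tailing time constant; ``tau = 0`` gives
    a symmetric Gaussian with tailing factor exactly 1.  Peak records are
    derived from the analytic shape (mode and fractional-height crossings of
    the EMG density), not from the sampled trace.
    """
    if not peaks:
        raise ValueError("at least one peak spec required")
    records = []
    end = 0.0
    for p in peaks:
        tr, sigma, tau = float(p["tr"]), float(p["sigma"]), float(p.get("tau", 0.0))
        if tr <= 0 or sigma <= 0 or tau < 0 or float(p.get("height", 1.0)) <= 0:
            raise ValueError("peak parameters must be positive (tau may be 0)")
        if tau == 0:
            mode = tr
            mu = tr
        else:
            # choose mu so the EMG mode lands at the requested retention time
            def mode_of(mu_):
                res = optimize.minimize_scalar(
                    lambda t: -_emg_pdf(t, mu_, sigma, tau),
                    bounds=(mu_ - 6 * sigma, mu_ + 6 * sigma + 10 * tau),
                    method="bounded",
                )
                return res.x

            mu = optimize.brentq(
                lambda m: mode_of(m) - tr, tr - 10 * (sigma + tau), tr + sigma
            )
            mode = tr
        records.append(_peak_record(mode, mu, sigma, tau, t0))
        end = max(end, tr + 8 * sigma + 12 * tau)

    times = np.arange(0.0, end, 1.0 / (60.0 * sample_rate_hz))
    trace = np.zeros_like(times)
    for p, rec in zip(peaks, records):
        tr, sigma, tau = float(p["tr"]), float(p["sigma"]), float(p.get("tau", 0.0))
        height = float(p.get("height", 1.0))
        mu = tr if tau == 0 else None
        if mu is None:
            # recover mu from the record: mode - mu offset is deterministic
            shape = lambda t: _emg_pdf(t, 0.0, sigma, tau)
            res = optimize.minimize_scalar(
                lambda t: -shape(t),
                bounds=(-6 * sigma, 6 * sigma + 10 * tau),
                method="bounded",
            )
            mu = tr - res.x
        dens = _emg_pdf(times, mu, sigma, tau)
        trace += height * dens / dens.max()
    if baseline_noise > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, baseline_noise, size=trace.shape)
    frame = pd.DataFrame({"time_min": times, "signal": trace})
    truth = {"peaks": peaks, "t0": t0, "baseline_noise": baseline_noise, "seed": seed}
    return frame, records, truth


def simulate_calibration(
    slope: float = 52000.0,
    intercept: float = 150.0,
    levels=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Linear calibration points: signal = slope*conc + intercept + noise.

    The default eight-level schedule spans 0.040-2.0 ug/mL; slope/intercept
    defaults are typical HPLC-UV peak-area scales.
    """
    if levels is None:
        levels = CALIBRATION_LEVELS_UG_ML
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0) or np.unique(levels).size != levels.size:
        raise ValueError("levels must be positive and distinct")
    rng = np.random.default_rng(seed)
    signal = slope * levels + intercept
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=levels.shape)
    frame = pd.DataFrame({"concentration_ug_ml": levels, "signal": signal})
    truth = {
        "slope": slope,
        "intercept": intercept,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return frame, truth
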
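"""Luminescence-decay kinetics and catalytic rate-constant estimation.

A luciferase reaction with enzyme concentration ``E`` (held constant — the
enzyme is a catalyst) and substrate concentration ``S(t)`` obeys

    dS/dt = -K * E * S,   S(0) = S0,

so the substrate decays exponentially with rate ``lambda = K * E`` and the
emitted photon flux, proportional to the reaction velocity, is

    flux(t) = alpha * K * E * S0 * exp(-K * E * t).

``K`` (M^-1 s^-1) is the catalytic rate constant and ``alpha`` an arbitrary
detector calibration (photons per mole of substrate consumed).  The rate
constant is estimated in two stages, mirroring how plate-reader decay data
are analysed in practice:

1. per trace, ordinary least squares of ``ln(flux)`` against time gives the
   decay rate magnitude ``lambda = K * E``;
2. across traces at different enzyme concentrations, OLS of ``lambda``
   against ``E`` gives ``K`` as the fitted slope, with a two-sided 95 %
   t-interval (n - 2 degrees of freedom).

Natural logarithms are used throughout so the fitted slope is ``K * E``
directly, with no base-conversion constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticParams",
    "LuminescenceTrace",
    "DecayFit",
    "RateConstantFit",
    "model_flux",
    "fit_log_slope",
    "estimate_rate_constant",
    "max_photon_flux",
    "time_above_threshold",
    "read_traces_csv",
    "write_traces_csv",
]

#: Default flux floor (photons/s) below which samples are treated as detector
#: noise and excluded from log-linear fitting.
DEFAULT_MIN_FLUX = 10.0


class InsufficientDataError(ValueError):
    """Fewer qualifying samples than a fit requires."""


class DegenerateDesignError(ValueError):
    """Regression design has no spread in the predictor."""


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the single-substrate luminescence decay model.

    Attributes
    ----------
    K : float
        Catalytic rate constant (M^-1 s^-1).
    E : float
        Enzyme concentration (M); constant over the reaction.
    S0 : float
        Initial substrate concentration (M).
    alpha : float
        Photons emitted per mole of substrate consumed times the detector
        scale (photons / M); an arbitrary calibration.
    """

    K: float
    E: float
    S0: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.E < 0:
            raise ValueError(f"E must be >= 0, got {self.E}")
        if self.S0 <= 0:
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass
class LuminescenceTrace:
    """One photon-flux time series at a known enzyme concentration."""

    times: np.ndarray  # seconds, strictly increasing
    flux: np.ndarray  # photons/s, non-negative
    enzyme_concentration: float  # M
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.times.shape != self.flux.shape:
            raise ValueError("times and flux must have equal length")
        if self.times.size < 3:
            raise ValueError("a trace needs at least 3 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.flux < 0):
            raise ValueError("flux must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DecayFit:
    """Log-linear fit of one trace: ``ln flux = intercept - slope * t``."""

    slope_magnitude: float  # s^-1, the fitted lambda = K * E
    intercept: float  # ln(photons/s)
    r_squared: float
    n_points_used: int
    window: tuple[float, float]  # [t_start, t_end] seconds


@dataclass(frozen=True)
class RateConstantFit:
    """Second-stage regression of decay rate against enzyme concentration."""

    K_hat: float  # M^-1 s^-1
    ci95: tuple[float, float]  # M^-1 s^-1
    intercept: float  # s^-1
    per_point: tuple[tuple[float, float], ...]  # (E, slope_magnitude)
    r_squared: float


def model_flux(params: KineticParams, times: Sequence[float]) -> LuminescenceTrace:
    """Evaluate the decay model ``alpha*K*E*S0*exp(-K*E*t)`` on a time grid."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    lam = params.K * params.E
    flux = params.alpha * lam * params.S0 * np.exp(-lam * t)
    return LuminescenceTrace(
        times=t, flux=flux, enzyme_concentration=params.E, label="model"
    )


def fit_log_slope(
    trace: LuminescenceTrace,
    window: Optional[tuple[float, float]] = None,
    min_flux: float = DEFAULT_MIN_FLUX,
) -> DecayFit:
    """OLS of natural-log flux against time; returns |slope| as the decay rate.

    With ``window=None`` the fit starts at the sample of maximum flux
    (discarding mixing transients before the peak) and runs to the end of the
    trace.  Samples with ``flux <= min_flux`` are excluded so near-zero
    detector counts do not dominate the log fit.
    """
    if window is None:
        i_peak = int(np.argmax(trace.flux))
        window = (float(trace.times[i_peak]), float(trace.times[-1]))
    t0, t1 = window
    sel = (trace.times >= t0) & (trace.times <= t1) & (trace.flux > min_flux)
    n = int(np.count_nonzero(sel))
    if n < 3:
        raise InsufficientDataError(
            f"only {n} samples with flux > {min_flux} in window [{t0}, {t1}]; need >= 3"
        )
    t = trace.times[sel]
    y = np.log(trace.flux[sel])
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # A flat log-flux trace is a perfect fit of a zero-slope line.
    r2 = 1.0 if ss_tot < 1e-300 else 1.0 - ss_res / ss_tot
    return DecayFit(
        slope_magnitude=abs(float(slope)),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points_used=n,
        window=(float(t0), float(t1)),
    )


def estimate_rate_constant(
    points: Sequence[tuple[float, float]],
) -> RateConstantFit:
    """Regress per-trace decay rates on enzyme concentration.

    The fitted slope is the rate constant ``K_hat`` (M^-1 s^-1); the
    intercept absorbs any concentration-independent baseline.  The 95 %
    confidence interval is the two-sided t-interval on the slope with
    ``n - 2`` degrees of freedom.
    """
    pts = [(float(e), float(s)) for e, s in points]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 (E, slope) points, got {len(pts)}"
        )
    E = np.array([p[0] for p in pts])
    lam = np.array([p[1] for p in pts])
    if np.ptp(E) == 0:
        raise DegenerateDesignError("all enzyme concentrations identical")
    res = stats.linregress(E, lam)
    n = len(pts)
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * res.stderr
    return RateConstantFit(
        K_hat=float(res.slope),
        ci95=(float(res.slope - half), float(res.slope + half)),
        intercept=float(res.intercept),
        per_point=tuple(pts),
        r_squared=float(res.rvalue**2),
    )


def max_photon_flux(trace: LuminescenceTrace) -> float:
    """Maximum photon flux over the trace (photons/s)."""
    return float(np.max(trace.flux))


def time_above_threshold(trace: LuminescenceTrace, threshold: float) -> float:
    """Total time (s) the flux spends above ``threshold``.

    Piecewise-linear interpolation between samples; a crossing inside a
    sampling interval contributes the interpolated sub-interval.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t = trace.times
    f = trace.flux
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        a, b = f[i] - threshold, f[i + 1] - threshold
        if a > 0 and b > 0:
            total += dt
        elif a > 0 >= b:
            total += dt * a / (a - b)
        elif a <= 0 < b:
            total += dt * b / (b - a)
    return float(total)


# ---------------------------------------------------------------------------
# Trace file I/O: CSV with header time_s,flux,enzyme_M,label

def write_traces_csv(traces: Sequence[LuminescenceTrace], path) -> None:
    """Write traces to a long-format CSV (``time_s,flux,enzyme_M,label``)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "flux": tr.flux,
                    "enzyme_M": tr.enzyme_concentration,
                    "label": tr.label,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[LuminescenceTrace]:
    """Read traces from a long-format CSV, one trace per distinct label."""
    df = pd.read_csv(path)
    required = {"time_s", "flux", "enzyme_M", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for label, g in df.groupby("label", sort=False):
        g = g.sort_values("time_s")
        enzymes = g["enzyme_M"].unique()
        if len(enzymes) != 1:
            raise ValueError(f"label {label!r} has multiple enzyme_M values")
        traces.append(
            LuminescenceTrace(
                times=g["time_s"].to_numpy(),
                flux=g["flux"].to_numpy(),
                enzyme_concentration=float(enzymes[0]),
                label=str(label),
            )
        )
    return traces
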
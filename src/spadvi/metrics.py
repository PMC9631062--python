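"""Step and spike response metrics: dF/F, SNR, F-V linearity, tau fits.

Definitions follow the standard voltage-imaging conventions: the baseline
fluorescence F is the mean over the first 100 ms of the trace; for each
response window dF is the window mean minus F; dF/F divides by F and SNR
divides by the standard deviation of the baseline. The F-V relationship
is summarized by a linear regression forced through the origin with the
uncentered coefficient of determination, and membrane time constants are
estimated by least-squares fits of a single exponential to the 100 ms
deflection after each step onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .pipeline import BinnedTrace

__all__ = [
    "StepWindows",
    "StepMetrics",
    "OriginRegression",
    "TauFit",
    "step_metrics",
    "fv_regression",
    "fit_tau",
    "spike_metrics",
    "SpikeMetrics",
]

# response windows in ms; the 460-520 ms window applies to voltage steps
# only (in current clamp it sits on the 0 pA step)
CURRENT_STEP_WINDOWS_MS = ((120.0, 180.0), (290.0, 350.0),
                           (630.0, 690.0), (800.0, 860.0))
VOLTAGE_STEP_WINDOWS_MS = ((120.0, 180.0), (290.0, 350.0), (460.0, 520.0),
                           (630.0, 690.0), (800.0, 860.0))


@dataclass(frozen=True)
class StepWindows:
    """Baseline and response windows in ms; half-open [start, end)."""

    baseline_ms: tuple = (0.0, 100.0)
    response_ms: tuple = CURRENT_STEP_WINDOWS_MS

    def __post_init__(self):
        wins = (self.baseline_ms,) + tuple(self.response_ms)
        for (a, b) in wins:
            if b <= a:
                raise ValueError(f"window ({a}, {b}) is empty")
        for (a0, b0), (a1, b1) in zip(wins, wins[1:]):
            if a1 < b0:
                raise ValueError("windows must be ordered and non-overlapping")

    @classmethod
    def current_clamp(cls) -> "StepWindows":
        return cls()

    @classmethod
    def voltage_clamp(cls) -> "StepWindows":
        return cls(response_ms=VOLTAGE_STEP_WINDOWS_MS)


@dataclass(frozen=True)
class StepMetrics:
    """Per-step dF, dF/F and SNR paired with ground-truth dV."""

    dF: np.ndarray
    dFF: np.ndarray
    snr: np.ndarray
    dV_mV: np.ndarray
    baseline_F: float
    baseline_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dV_mV": self.dV_mV, "dF": self.dF,
                             "dFF": self.dFF, "snr": self.snr})


@dataclass(frozen=True)
class OriginRegression:
    """Linear regression forced through the origin.

    ``slope = sum(xy)/sum(x^2)``; R^2 is the uncentered coefficient of
    determination ``1 - SS_res / sum(y^2)``, the standard convention for
    through-origin fits.
    """

    slope: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class TauFit:
    """Result of fitting ``y(t) = A + B exp(-t/tau)``."""

    tau_ms: float
    asymptote: float
    amplitude: float
    rmse: float
    success: bool
    message: str = ""


def _window_slice(win_ms: tuple, rate_Hz: float, n: int, name: str) -> slice:
    # half-open [start, end) in ms mapped to 0-based samples
    i0 = int(np.ceil(win_ms[0] / 1000.0 * rate_Hz - 1e-9))
    i1 = int(np.ceil(win_ms[1] / 1000.0 * rate_Hz - 1e-9))
    if i1 > n or i0 >= i1:
        raise ValueError(f"{name} window {win_ms} ms exceeds trace "
                         f"({n} samples at {rate_Hz:g} Hz)")
    return slice(i0, i1)


def step_metrics(trace: BinnedTrace, dV_mV, windows: StepWindows | None = None
                 ) -> StepMetrics:
    """Per-step dF/F and SNR of a (typically 100 Hz) binned step trace."""
    windows = windows or StepWindows()
    dV = np.asarray(dV_mV, dtype=float)
    if dV.size != len(windows.response_ms):
        raise ValueError("need one ground-truth dV per response window")
    v = trace.values
    rate = trace.effective_rate_Hz
    base = v[_window_slice(windows.baseline_ms, rate, v.size, "baseline")]
    f0 = float(base.mean())
    sd = float(base.std(ddof=1))
    dF = np.array([v[_window_slice(w, rate, v.size, "response")].mean() - f0
                   for w in windows.response_ms])
    snr = dF / sd if sd > 0 else np.full_like(dF, np.nan)
    return StepMetrics(dF=dF, dFF=dF / f0, snr=snr, dV_mV=dV,
                       baseline_F=f0, baseline_sd=sd)


def fv_regression(dV_mV, dFF) -> OriginRegression:
    """Through-origin regression of dF/F on dV."""
    x = np.asarray(dV_mV, dtype=float)
    y = np.asarray(dFF, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all dV are zero; slope undefined")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return OriginRegression(slope=slope, r_squared=r2, n=x.size)


def fit_tau(segment, rate_Hz: float, max_iter: int = 200) -> TauFit:
    """Fit a single-exponential relaxation to a post-onset segment.

    Initialization from the endpoints (asymptote from the last value,
    amplitude from first minus last, tau from the time to 63% of the
    range). Fits outside (0.1 ms, 1 s) or non-convergent fits return a
    failure result rather than raising.
    """
    y = np.asarray(segment, dtype=float)
    if y.size < 5:
        return TauFit(np.nan, np.nan, np.nan, np.nan, False,
                      "segment shorter than 5 samples")
    t = np.arange(y.size) / rate_Hz
    a0, b0 = y[-1], y[0] - y[-1]
    if abs(b0) < 1e-12 * max(1.0, abs(a0)):
        return TauFit(np.nan, float(a0), 0.0, float(y.std()), False,
                      "degenerate amplitude (flat segment)")
    # time at which the deflection has covered 63% of its range
    frac = (y - y[0]) / (y[-1] - y[0])
    idx = np.argmax(frac >= 0.632)
    tau0 = t[idx] if idx > 0 else t[y.size // 3]
    tau0 = max(tau0, 1.0 / rate_Hz)

    def model(tt, a, b, tau):
        return a + b * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, b0, tau0),
                            bounds=([-np.inf, -np.inf, 1e-6],
                                    [np.inf, np.inf, 10.0]),
                            max_nfev=max_iter * 10, xtol=1e-8, ftol=1e-8)
    except (RuntimeError, ValueError) as exc:
        return TauFit(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    a, b, tau = popt
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    tau_ms = float(tau) * 1000.0
    if not (0.1 < tau_ms < 1000.0):
        return TauFit(tau_ms, float(a), float(b), rmse, False,
                      f"tau {tau_ms:.3g} ms outside (0.1 ms, 1 s)")
    return TauFit(tau_ms, float(a), float(b), rmse, True)


@dataclass(frozen=True)
class SpikeMetrics:
    """Per-spike and trace-level dF/F and SNR."""

    dFF: np.ndarray
    snr: np.ndarray
    mean_dFF: float
    mean_snr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dFF": self.dFF, "snr": self.snr})


def spike_metrics(trace: BinnedTrace, peak_indices, baseline_F: float,
                  baseline_sd: float, baseline_subtracted: bool = True
                  ) -> SpikeMetrics:
    """dF/F and SNR per detected spike peak.

    dF is the peak intensity minus the baseline fluorescence of the same
    optical trace; dF/F divides by the baseline fluorescence and SNR by
    its standard deviation; trace-level values are means over spikes.
    On a spike-band trace (high-passed by subtraction) the peak values
    are already baseline-free, so ``baseline_subtracted=True`` (default)
    skips the subtraction; pass False when reading peaks off a raw trace.
    """
    idx = np.asarray(peak_indices, dtype=int)
    if idx.size == 0:
        return SpikeMetrics(np.empty(0), np.empty(0), np.nan, np.nan)
    peaks = trace.values[idx]
    dF = peaks if baseline_subtracted else peaks - baseline_F
    dff = dF / baseline_F
    snr = dF / baseline_sd
    return SpikeMetrics(dFF=dff, snr=snr,
                        mean_dFF=float(dff.mean()), mean_snr=float(snr.mean()))
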
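"""ROI trace extraction and the filtering / binning / detrending chain.

The raw currency of the analysis is the per-plane ROI-summed photon count
at the native frame rate. Because binary pixels saturate, trace values are
log-corrected (``-M ln(1 - counts/M)`` for an M-pixel ROI) before
filtering; high-frequency shot noise is removed with a zero-phase 2 kHz
low-pass, and temporal binning (non-overlapping means of N consecutive
planes) sets the effective frame rate for each analysis: 100 Hz for
subthreshold events, 1 kHz for spikes.

Every processing step is appended to the trace's processing log so a
finished trace carries its own provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .camera import BitPlaneStack

__all__ = [
    "ROIMask",
    "PhotonTrace",
    "BinnedTrace",
    "extract_roi_trace",
    "log_correct_trace",
    "lowpass",
    "temporal_bin",
    "effective_frame_rate",
    "detrend_linear",
    "isolate_spike_band",
]


@dataclass(frozen=True)
class ROIMask:
    """Boolean raster of member pixels, within sensor bounds."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("ROI mask must be 2-D and non-empty")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @classmethod
    def from_pixels(cls, pixels, shape) -> "ROIMask":
        m = np.zeros(shape, dtype=bool)
        rows, cols = zip(*pixels)
        m[list(rows), list(cols)] = True
        return cls(m)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.mask.astype(np.uint8), fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "ROIMask":
        return cls(np.loadtxt(path, delimiter=",") != 0)


@dataclass(frozen=True)
class PhotonTrace:
    """Per-plane ROI-summed counts at the native frame rate."""

    counts: np.ndarray
    frame_rate_Hz: float
    n_roi_pixels: int
    corrected: bool = False
    log: tuple = ()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or np.any(c < 0):
            raise ValueError("counts must be a 1-D nonnegative array")
        if not self.corrected and np.any(c > self.n_roi_pixels):
            raise ValueError("raw counts cannot exceed the ROI pixel count")
        object.__setattr__(self, "counts", c)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.counts.size) / self.frame_rate_Hz


@dataclass(frozen=True)
class BinnedTrace:
    """Trace after filtering/binning, with provenance of processing steps."""

    values: np.ndarray
    effective_rate_Hz: float
    bin_factor: int
    log: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def times(self) -> np.ndarray:
        # bin-center convention: bin k covers [k, k+1)/rate
        return (np.arange(self.values.size) + 0.5) / self.effective_rate_Hz

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header="time_s,value", comments="")


def extract_roi_trace(stack: BitPlaneStack, roi: ROIMask) -> PhotonTrace:
    """Sum counts within the ROI for each bit plane."""
    if roi.shape != (stack.height, stack.width):
        rr, cc = np.nonzero(roi.mask)
        bad = [(int(r), int(c)) for r, c in zip(rr, cc)
               if r >= stack.height or c >= stack.width][:5]
        raise ValueError(f"ROI shape {roi.shape} does not match stack "
                         f"{(stack.height, stack.width)}; offending pixels "
                         f"include {bad}")
    counts = stack.planes[:, roi.mask].sum(axis=1).astype(float)
    return PhotonTrace(counts=counts, frame_rate_Hz=stack.frame_rate_Hz,
                       n_roi_pixels=roi.n_pixels, corrected=False,
                       log=("extract_roi",))


def log_correct_trace(trace: PhotonTrace) -> PhotonTrace:
    """Invert the ROI-summed logarithmic pixel response.

    ``counts' = -M ln(1 - counts/M)``; a fully saturated plane
    (counts = M) is capped at ``-M ln(1/(2M))``.
    """
    if trace.corrected:
        raise ValueError("trace is already corrected")
    m = trace.n_roi_pixels
    if m == 0:
        raise ValueError("ROI has no pixels")
    frac = np.minimum(trace.counts / m, 1.0 - 1.0 / (2 * m))
    out = -m * np.log1p(-frac)
    return replace(trace, counts=out, corrected=True,
                   log=trace.log + ("log_correct",))


def _butter_lowpass(values: np.ndarray, cutoff_Hz: float, rate_Hz: float
                    ) -> np.ndarray:
    if cutoff_Hz >= rate_Hz / 2:
        raise ValueError(f"cutoff {cutoff_Hz:g} Hz >= Nyquist {rate_Hz / 2:g} Hz")
    sos = sps.butter(4, cutoff_Hz, btype="low", fs=rate_Hz, output="sos")
    return sps.sosfiltfilt(sos, values)


def lowpass(trace: PhotonTrace, cutoff_Hz: float) -> PhotonTrace:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    out = _butter_lowpass(trace.counts, cutoff_Hz, trace.frame_rate_Hz)
    return replace(trace, counts=np.maximum(out, 0.0), corrected=True,
                   log=trace.log + (f"lowpass:{cutoff_Hz:g}Hz",))


def effective_frame_rate(native_Hz: float, bin_factor: int) -> float:
    """Effective frame rate after binning N consecutive planes."""
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    return native_Hz / bin_factor


def temporal_bin(trace: PhotonTrace | BinnedTrace, bin_factor: int) -> BinnedTrace:
    """Average non-overlapping groups of N consecutive values.

    Trailing samples that do not fill a bin are dropped; the effective
    rate is the source rate divided by N.
    """
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    if isinstance(trace, BinnedTrace):
        values, rate, log = trace.values, trace.effective_rate_Hz, trace.log
        prior = trace.bin_factor
    else:
        values, rate, log = trace.counts, trace.frame_rate_Hz, trace.log
        prior = 1
    n = values.size // bin_factor
    if n == 0:
        raise ValueError("trace shorter than one bin")
    binned = values[:n * bin_factor].reshape(n, bin_factor).mean(axis=1)
    return BinnedTrace(values=binned,
                       effective_rate_Hz=effective_frame_rate(rate, bin_factor),
                       bin_factor=prior * bin_factor,
                       log=log + (f"bin:{bin_factor}",))


def detrend_linear(trace: BinnedTrace) -> BinnedTrace:
    """Subtract the ordinary least-squares straight line (and mean)."""
    if trace.values.size < 2:
        raise ValueError("need at least 2 samples to detrend")
    out = sps.detrend(trace.values, type="linear")
    return replace(trace, values=out, log=trace.log + ("detrend:linear",))


def isolate_spike_band(trace: PhotonTrace, target_rate_Hz: float = 1000.0,
                       subtract_cutoff_Hz: float = 10.0, invert: bool = False,
                       mode: str = "subtract") -> BinnedTrace:
    """Isolate the spike band of a (2 kHz low-passed) native-rate trace.

    Default mode removes subthreshold events and baseline drift by
    subtracting a 10 Hz low-passed copy (a high-pass by subtraction),
    then bins to the target effective rate (1 kHz). ``mode="lowpass"``
    instead keeps the 10 Hz low-passed copy itself. ``invert`` flips the
    sign so spikes from a negatively coupled indicator are positive-going.
    """
    slow = _butter_lowpass(trace.counts, subtract_cutoff_Hz, trace.frame_rate_Hz)
    if mode == "subtract":
        band = trace.counts - slow
        step = f"spikeband:subtract@{subtract_cutoff_Hz:g}Hz"
    elif mode == "lowpass":
        band = slow
        step = f"spikeband:lowpass@{subtract_cutoff_Hz:g}Hz"
    else:
        raise ValueError(f"unknown spike-band mode {mode!r}")
    if invert:
        band = -band
        step += ":inverted"
    bin_factor = max(1, int(round(trace.frame_rate_Hz / target_rate_Hz)))
    # bin the band directly (values may be negative, so bypass PhotonTrace)
    n = band.size // bin_factor
    binned = band[:n * bin_factor].reshape(n, bin_factor).mean(axis=1)
    return BinnedTrace(values=binned,
                       effective_rate_Hz=effective_frame_rate(
                           trace.frame_rate_Hz, bin_factor),
                       bin_factor=bin_factor,
                       log=trace.log + (step, f"bin:{bin_factor}"))
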
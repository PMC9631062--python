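"""Spike detection, ground-truth scoring, and ensemble synchrony statistics.

Detection runs on the positive-going spike-band trace (1 kHz effective):
a rolling-median baseline with a rolling-MAD noise scale yields candidate
peaks exceeding both an SD-multiple threshold and an absolute amplitude
floor, pruned by a refractory interval. Synchrony between cells is
quantified by a peristimulus time histogram (PSTH) of one cell's spikes
around another's, and by the normalized cross-correlation of their
subthreshold traces; both are compared against shuffle nulls (spike-time
randomization preserving counts, or re-pairing of traces from independent
cells), summarized by the per-bin mean and 5-95% percentile envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .neuron import SpikeTrain
from .pipeline import BinnedTrace

__all__ = [
    "SpikeTrain",
    "DetectorParams",
    "DetectionScore",
    "NullBand",
    "detect_spikes",
    "score_detection",
    "psth",
    "psth_null",
    "subthreshold_xcorr",
    "xcorr_null",
]


@dataclass(frozen=True)
class DetectorParams:
    """Three-parameter spike detector settings (plus a refractory gap)."""

    window_samples: int = 51
    sd_threshold: float = 4.0
    min_amplitude: float = 1e-9
    refractory_ms: float = 5.0

    def __post_init__(self):
        if min(self.window_samples, self.sd_threshold,
               self.min_amplitude, self.refractory_ms) <= 0:
            raise ValueError("all detector parameters must be positive")


@dataclass(frozen=True)
class DetectionScore:
    """Confusion counts from matching detected to ground-truth spikes."""

    true_positives: int
    false_negatives: int
    false_positives: int
    matches: tuple  # (truth_time, detected_time) pairs
    tolerance_ms: float

    @property
    def tp_rate(self) -> float:
        n = self.true_positives + self.false_negatives
        return self.true_positives / n if n else np.nan


@dataclass(frozen=True)
class NullBand:
    """Observed statistic with a shuffle-null mean and 5-95% envelope."""

    centers: np.ndarray  # bin centers (s) or lags (s)
    observed: np.ndarray
    null_mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    n_shuffles: int

    def outside_band(self) -> np.ndarray:
        return (self.observed < self.p5) | (self.observed > self.p95)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "observed": self.observed,
                             "null_mean": self.null_mean, "p5": self.p5,
                             "p95": self.p95})


def detect_spikes(spike_band: BinnedTrace, params: DetectorParams = DetectorParams()
                  ) -> SpikeTrain:
    """Detect positive-going spikes in a spike-band trace.

    The local baseline is a rolling median over ``window_samples``; the
    noise scale is a robust SD of the residual from that baseline,
    estimated from the negative residual side only (spikes are
    positive-going, so even dense spiking cannot inflate it). Local
    maxima of
    the residual exceeding both ``sd_threshold`` x noise and
    ``min_amplitude`` are kept; of any pair closer than the refractory
    gap, the larger survives. Peaks within half a window of either end
    are discarded (zero-phase filter edge transients live there).
    """
    x = spike_band.values
    if params.window_samples >= x.size:
        raise ValueError(f"window_samples {params.window_samples} >= trace "
                         f"length {x.size}")
    w = params.window_samples
    baseline = ndimage.median_filter(x, size=w, mode="nearest")
    resid = x - baseline
    neg = resid[resid < 0]
    if neg.size == 0:
        neg = resid - np.max(resid)  # degenerate: no negative side
    # median(|X|) = 0.674 sigma for centered Gaussian X, one-sided
    noise = max(float(np.median(-neg)) / 0.6745, 1e-12)
    peaks, _ = sps.find_peaks(resid)
    guard = w // 2
    peaks = peaks[(peaks >= guard) & (peaks < x.size - guard)]
    peaks = peaks[(resid[peaks] > params.sd_threshold * noise)
                  & (resid[peaks] > params.min_amplitude)]
    # refractory pruning: among peaks closer than the gap, keep the larger
    gap = int(round(params.refractory_ms / 1000.0 * spike_band.effective_rate_Hz))
    if gap > 0 and peaks.size:
        order = peaks[np.argsort(resid[peaks])[::-1]]
        kept: list[int] = []
        for p in order:
            if all(abs(p - q) >= gap for q in kept):
                kept.append(p)
        peaks = np.sort(np.asarray(kept, dtype=int))
    times = peaks / spike_band.effective_rate_Hz
    dur = x.size / spike_band.effective_rate_Hz
    return SpikeTrain(times=times, duration_s=dur, source="detected")


def score_detection(detected: SpikeTrain, truth: SpikeTrain,
                    tolerance_ms: float = 2.0) -> DetectionScore:
    """Greedy nearest-first one-to-one matching within a tolerance."""
    det, tru = detected.times, truth.times
    pairs = []
    tol = tolerance_ms / 1000.0
    for i, tt in enumerate(tru):
        for j, dt in enumerate(det):
            d = abs(dt - tt)
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_t, used_d, matches = set(), set(), []
    for d, i, j in pairs:
        if i not in used_t and j not in used_d:
            used_t.add(i)
            used_d.add(j)
            matches.append((float(tru[i]), float(det[j])))
    tp = len(matches)
    return DetectionScore(true_positives=tp,
                          false_negatives=len(tru) - tp,
                          false_positives=len(det) - tp,
                          matches=tuple(matches), tolerance_ms=tolerance_ms)


def _psth_counts(reference: np.ndarray, target: np.ndarray,
                 edges: np.ndarray) -> np.ndarray:
    counts = np.zeros(edges.size - 1)
    for r in reference:
        lags = target - r
        lags = lags[(lags >= edges[0]) & (lags < edges[-1])]
        if lags.size:
            counts += np.histogram(lags, bins=edges)[0]
    return counts


def _psth_edges(window_s: float, bin_s: float) -> np.ndarray:
    n_bins = window_s / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window_s must be an integer multiple of bin_s")
    n_bins = int(round(n_bins))
    # bins tile the window with zero lag at a bin edge, so exact
    # coincidences and integer-bin shifts land unambiguously in one bin
    return (np.arange(n_bins + 1) - n_bins // 2) * bin_s


def psth(reference: SpikeTrain, target: SpikeTrain,
         window_s: float = 0.050, bin_s: float = 0.002
         ) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram of target spikes around reference spikes.

    For every reference spike, target spikes with lag inside the centered
    window are counted in half-open bins (bin edges at multiples of
    ``bin_s`` with zero lag at an edge); counts are summed over all
    reference spikes. Returns (bin_centers_s, counts).
    """
    if len(reference) == 0:
        raise ValueError("reference train has no spikes")
    edges = _psth_edges(window_s, bin_s)
    counts = _psth_counts(reference.times, target.times, edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts


def _shuffle_train(train: SpikeTrain, rng: np.random.Generator,
                   scheme: str) -> np.ndarray:
    n = len(train)
    if scheme == "uniform":
        return np.sort(rng.uniform(0, train.duration_s, size=n))
    if scheme == "isi":
        isi = np.diff(np.concatenate([[0.0], train.times]))
        return np.cumsum(rng.permutation(isi))
    raise ValueError(f"unknown shuffle scheme {scheme!r}")


def psth_null(reference: SpikeTrain, target: SpikeTrain,
              window_s: float = 0.050, bin_s: float = 0.002,
              n_shuffles: int = 100, seed: int = 0,
              scheme: str = "uniform") -> NullBand:
    """PSTH with a spike-time shuffle null band.

    Each shuffle redraws both trains' spike times uniformly over the
    recording (preserving counts; ``scheme="isi"`` permutes inter-spike
    intervals instead), recomputes the PSTH, and the band is the per-bin
    mean and 5-95% percentiles over shuffles.
    """
    if n_shuffles < 20:
        warnings.warn("fewer than 20 shuffles: percentile band unstable",
                      stacklevel=2)
    centers, observed = psth(reference, target, window_s, bin_s)
    edges = _psth_edges(window_s, bin_s)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, centers.size))
    for k in range(n_shuffles):
        ref_s = _shuffle_train(reference, rng, scheme)
        tar_s = _shuffle_train(target, rng, scheme)
        null[k] = _psth_counts(ref_s, tar_s, edges)
    return NullBand(centers=centers, observed=observed,
                    null_mean=null.mean(axis=0),
                    p5=np.percentile(null, 5, axis=0),
                    p95=np.percentile(null, 95, axis=0),
                    n_shuffles=n_shuffles)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("trace has zero variance; cannot normalize")
    return (x - x.mean()) / sd


def subthreshold_xcorr(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Normalized full-lag cross-correlation of two subthreshold traces.

    Both traces are z-scored and correlated over all lags with the biased
    1/n normalization, so a trace's autocorrelation at lag 0 equals 1.
    Inputs are equal-length 1-D arrays or BinnedTraces at equal rates;
    lists of per-epoch pairs are averaged. Returns (lags_samples, corr).
    """
    if isinstance(a, (list, tuple)) and not isinstance(a, np.ndarray):
        curves = [subthreshold_xcorr(ai, bi) for ai, bi in zip(a, b)]
        lags = curves[0][0]
        return lags, np.mean([c for _, c in curves], axis=0)
    rate = None
    if isinstance(a, BinnedTrace):
        if isinstance(b, BinnedTrace) and not np.isclose(
                a.effective_rate_Hz, b.effective_rate_Hz):
            raise ValueError("traces must share an effective rate")
        rate = a.effective_rate_Hz
        a, b = a.values, b.values if isinstance(b, BinnedTrace) else b
    a = np.asarray(a, dtype=float)
    b = np.asarray(b.values if isinstance(b, BinnedTrace) else b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    za, zb = _zscore(a), _zscore(b)
    corr = sps.correlate(za, zb, mode="full") / n
    lags = sps.correlation_lags(n, n, mode="full").astype(float)
    if rate is not None:
        lags = lags / rate
    return lags, corr


def xcorr_null(trace_bank, n_pairs: int = 100, seed: int = 0) -> NullBand:
    """Cross-cell null band for the subthreshold cross-correlation.

    ``trace_bank`` maps a source id to a list of traces (1-D arrays or
    BinnedTraces) from that independent source; ``n_pairs`` random
    cross-source pairings yield the per-lag mean and 5-95% band.
    """
    sources = list(trace_bank)
    if len(sources) < 2:
        raise ValueError("need traces from >= 2 independent sources")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_pairs):
        s1, s2 = rng.choice(len(sources), size=2, replace=False)
        t1 = trace_bank[sources[s1]]
        t2 = trace_bank[sources[s2]]
        a = t1[rng.integers(len(t1))]
        b = t2[rng.integers(len(t2))]
        lags, c = subthreshold_xcorr(a, b)
        curves.append(c)
    null = np.asarray(curves)
    return NullBand(centers=lags, observed=np.full(lags.size, np.nan),
                    null_mean=null.mean(axis=0),
                    p5=np.percentile(null, 5, axis=0),
                    p95=np.percentile(null, 95, axis=0),
                    n_shuffles=n_pairs)
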
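"""Ground-truth membrane-potential simulation.

Produces the voltage traces the imaging simulator consumes: passive
(single-compartment RC) responses to current/voltage step protocols,
stereotyped action-potential trains evoked by brief current pulses, and
multi-cell ensembles with millisecond-scale burst synchrony of the kind
seen during 4-AP-induced seizure-like events.

The membrane model is deliberately passive: each current step relaxes
exponentially toward ``V_rest + I*R`` with the membrane time constant.
Action potentials are stereotyped waveform instances (a fast rise and an
exponential decay, ~1-2 ms total) stamped at pulse onsets, not the output
of conductance-based dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoltageTrace",
    "StepProtocol",
    "PulseTrainProtocol",
    "CellMembraneModel",
    "EnsembleModel",
    "simulate_step_response",
    "simulate_spike_train",
    "simulate_ensemble",
    "SpikeTrain",
]


@dataclass(frozen=True)
class VoltageTrace:
    """Membrane potential on a uniform time grid.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, uniform grid starting at 0.
    values : ndarray
        Membrane potential in mV.
    sample_rate : float
        Sampling rate in Hz; the grid step is ``1/sample_rate``.
    """

    times: np.ndarray
    values: np.ndarray
    sample_rate: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape or t.size < 2:
            raise ValueError("times/values must be 1-D, equal length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage values must be finite")
        step = 1.0 / self.sample_rate
        if not np.allclose(np.diff(t), step, rtol=1e-6, atol=1e-12):
            raise ValueError("times must increase with constant step 1/sample_rate")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def duration_s(self) -> float:
        return self.times.size / self.sample_rate

    def to_csv(self, path) -> None:
        """Write as 2-column CSV (time_s, mV)."""
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header="time_s,mV", comments="")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times for one cell."""

    times: np.ndarray
    duration_s: float
    source: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] >= self.duration_s):
            raise ValueError("spike times must lie in [0, duration_s)")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    def to_text(self, path) -> None:
        """One spike time (seconds) per line."""
        np.savetxt(path, self.times, fmt="%.9f")

    @classmethod
    def from_text(cls, path, duration_s: float, source: str = "") -> "SpikeTrain":
        times = np.atleast_1d(np.loadtxt(path, dtype=float))
        return cls(times=times, duration_s=duration_s, source=source)


@dataclass(frozen=True)
class StepProtocol:
    """Square-step stimulation: a baseline then consecutive constant steps.

    ``step_levels`` are pA in current mode and absolute command mV in
    voltage mode (the cell is held at ``holding_mV`` during baseline).
    Each step is followed by ``inter_step_s`` of recovery at rest/holding;
    the default 70 ms matches measurement windows spaced 170 ms apart for
    100 ms steps (set 0 for back-to-back steps).
    """

    baseline_s: float = 0.1
    step_levels: tuple = (-200.0, -100.0, 0.0, 100.0, 200.0)
    step_duration_s: float = 0.1
    inter_step_s: float = 0.07
    mode: str = "current"
    holding_mV: float = -70.0

    def __post_init__(self):
        if self.baseline_s <= 0 or self.step_duration_s <= 0:
            raise ValueError("baseline_s and step_duration_s must be positive")
        if self.inter_step_s < 0:
            raise ValueError("inter_step_s must be >= 0")
        if not self.step_levels:
            raise ValueError("step_levels must be non-empty")
        if self.mode not in ("current", "voltage"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def duration_s(self) -> float:
        per_step = self.step_duration_s + self.inter_step_s
        return self.baseline_s + len(self.step_levels) * per_step

    def step_onsets(self) -> np.ndarray:
        per_step = self.step_duration_s + self.inter_step_s
        return self.baseline_s + np.arange(len(self.step_levels)) * per_step

    @classmethod
    def default_current(cls) -> "StepProtocol":
        """-200..200 pA in 100 pA increments, 100 ms each, 100 ms baseline."""
        return cls()

    @classmethod
    def default_voltage(cls) -> "StepProtocol":
        """-50..30 mV command in 20 mV increments, held at -70 mV."""
        return cls(step_levels=(-50.0, -30.0, -10.0, 10.0, 30.0), mode="voltage")


@dataclass(frozen=True)
class PulseTrainProtocol:
    """Train of brief suprathreshold current pulses (e.g., 10 x 2 nA, 2 ms)."""

    n_pulses: int = 10
    amplitude_nA: float = 2.0
    pulse_width_ms: float = 2.0
    frequency_Hz: float = 25.0
    onset_s: float = 0.1

    def __post_init__(self):
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.frequency_Hz <= 0:
            raise ValueError("frequency_Hz must be positive")
        if self.pulse_width_ms >= 1000.0 / self.frequency_Hz:
            raise ValueError("pulse width exceeds the inter-pulse interval")

    def pulse_onsets(self) -> np.ndarray:
        return self.onset_s + np.arange(self.n_pulses) / self.frequency_Hz

    @property
    def duration_s(self) -> float:
        return self.onset_s + self.n_pulses / self.frequency_Hz + 0.1


@dataclass(frozen=True)
class CellMembraneModel:
    """Passive single-compartment cell with a stereotyped spike template.

    The spike template rises linearly over ``spike_rise_ms`` to
    ``spike_peak_mV`` above rest and decays exponentially with
    ``spike_decay_ms`` (truncated at 5 decay constants), giving a ~ms-wide
    action potential.
    """

    resistance_MOhm: float = 100.0
    tau_membrane_ms: float = 15.0
    resting_mV: float = -70.0
    spike_peak_mV: float = 80.0
    spike_rise_ms: float = 1.0
    spike_decay_ms: float = 1.5

    def __post_init__(self):
        if self.resistance_MOhm <= 0 or self.tau_membrane_ms <= 0:
            raise ValueError("resistance and tau must be positive")
        if self.spike_peak_mV <= 0:
            raise ValueError("spike peak must be positive")

    def spike_waveform(self, sample_rate: float) -> tuple[np.ndarray, int]:
        """Return (waveform mV relative to rest, index of the peak sample)."""
        dt_ms = 1000.0 / sample_rate
        n_rise = max(1, int(round(self.spike_rise_ms / dt_ms)))
        n_decay = max(1, int(round(5.0 * self.spike_decay_ms / dt_ms)))
        rise = np.linspace(0.0, 1.0, n_rise, endpoint=False)
        decay = np.exp(-np.arange(n_decay + 1) * dt_ms / self.spike_decay_ms)
        w = self.spike_peak_mV * np.concatenate([rise, decay])
        return w, n_rise

    def spike_extent_s(self) -> float:
        return (self.spike_rise_ms + 5.0 * self.spike_decay_ms) / 1000.0


@dataclass(frozen=True)
class EnsembleModel:
    """Multi-cell ensemble with shared bursts and private noise.

    Common burst onsets are a Poisson process; within a burst every cell
    fires the same template spike times plus independent Gaussian jitter
    (SD ``sync_jitter_ms``), on top of independent background spiking.
    Subthreshold activity is a shared burst-locked depolarization envelope
    (one alpha function per burst) plus private Gaussian noise.
    """

    n_cells: int = 2
    burst_rate_Hz: float = 0.5
    spikes_per_burst: int = 5
    intra_burst_interval_ms: float = 12.0
    sync_jitter_ms: float = 1.0
    independent_rate_Hz: float = 1.0
    subthreshold_common_amp_mV: float = 10.0
    subthreshold_noise_mV: float = 0.5
    duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if min(self.burst_rate_Hz, self.independent_rate_Hz) < 0:
            raise ValueError("rates must be >= 0")
        if self.sync_jitter_ms < 0:
            raise ValueError("sync_jitter_ms must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def _check_rate(sample_rate: float, minimum: float) -> None:
    if not np.isfinite(sample_rate) or sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    if sample_rate < minimum:
        raise ValueError(f"sample_rate must be >= {minimum:g} Hz")


# settling constant applied to voltage-clamp command steps (clean steps,
# limited only by a short fixed electrode/membrane settling time)
VCLAMP_SETTLE_MS = 1.0


def simulate_step_response(protocol: StepProtocol, cell: CellMembraneModel,
                           sample_rate: float = 20_000.0) -> VoltageTrace:
    """Simulate the passive response to a step protocol.

    In current mode each step relaxes exponentially from the voltage at
    step onset toward ``V_rest + I*R`` with the membrane time constant; in
    voltage mode the command is followed with a 1 ms settling constant.
    """
    _check_rate(sample_rate, 1000.0)
    dt = 1.0 / sample_rate
    n_total = int(round(protocol.duration_s * sample_rate))
    t = np.arange(n_total) * dt
    v = np.empty(n_total)

    if protocol.mode == "current":
        rest = cell.resting_mV
        tau_s = cell.tau_membrane_ms / 1000.0
        levels = [rest + i_pA * cell.resistance_MOhm * 1e-3
                  for i_pA in protocol.step_levels]
    else:
        rest = protocol.holding_mV
        tau_s = VCLAMP_SETTLE_MS / 1000.0
        levels = list(protocol.step_levels)

    targets = [rest]
    bounds = [0.0, protocol.baseline_s]
    for lv in levels:
        targets.append(lv)
        bounds.append(bounds[-1] + protocol.step_duration_s)
        if protocol.inter_step_s > 0:
            targets.append(rest)
            bounds.append(bounds[-1] + protocol.inter_step_s)

    v_start = rest
    for seg, target in enumerate(targets):
        i0 = int(round(bounds[seg] * sample_rate))
        i1 = int(round(bounds[seg + 1] * sample_rate))
        tt = (np.arange(i1 - i0)) * dt
        v[i0:i1] = target + (v_start - target) * np.exp(-tt / tau_s)
        if i1 > i0:
            v_start = target + (v_start - target) * np.exp(-(i1 - i0) * dt / tau_s)
    return VoltageTrace(times=t, values=v, sample_rate=sample_rate)


def _stamp_spikes(v: np.ndarray, spike_times: np.ndarray,
                  cell: CellMembraneModel, sample_rate: float) -> None:
    """Add spike waveform instances in place, peaks at ``spike_times``."""
    w, peak_idx = cell.spike_waveform(sample_rate)
    n = v.size
    for st in spike_times:
        p = int(round(st * sample_rate))
        lo, hi = p - peak_idx, p - peak_idx + w.size
        wlo, whi = max(0, -lo), w.size - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if hi > lo:
            v[lo:hi] += w[wlo:whi]


def simulate_spike_train(protocol: PulseTrainProtocol, cell: CellMembraneModel,
                         sample_rate: float = 20_000.0
                         ) -> tuple[VoltageTrace, SpikeTrain]:
    """Simulate an evoked spike train: one stereotyped AP per current pulse.

    The spike waveform peak is aligned to each pulse onset, and those peak
    times are returned as the ground-truth spike train.
    """
    _check_rate(sample_rate, 10_000.0)
    interval_s = 1.0 / protocol.frequency_Hz
    extent = cell.spike_extent_s()
    if protocol.n_pulses > 1 and extent > interval_s:
        raise ValueError(
            f"spike waveform ({extent * 1e3:.1f} ms) overlaps successive pulses "
            f"at {protocol.frequency_Hz:g} Hz (interval {interval_s * 1e3:.1f} ms); "
            f"pulses 0 and 1 conflict")
    onsets = protocol.pulse_onsets()
    n_total = int(round(protocol.duration_s * sample_rate))
    t = np.arange(n_total) / sample_rate
    v = np.full(n_total, cell.resting_mV)
    _stamp_spikes(v, onsets, cell, sample_rate)
    train = SpikeTrain(times=onsets, duration_s=protocol.duration_s, source="truth")
    return VoltageTrace(times=t, values=v, sample_rate=sample_rate), train


def _alpha_envelope(t: np.ndarray, onsets: np.ndarray, amp_mV: float,
                    rise_s: float = 0.020, decay_s: float = 0.200) -> np.ndarray:
    """Sum of peak-normalized alpha-like (double-exponential) bumps."""
    env = np.zeros_like(t)
    if decay_s <= rise_s:
        raise ValueError("decay must exceed rise")
    # peak of exp(-t/d) - exp(-t/r) for normalization
    tp = (np.log(decay_s) - np.log(rise_s)) / (1 / rise_s - 1 / decay_s)
    peak = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    for on in onsets:
        tt = t - on
        m = tt > 0
        env[m] += amp_mV / peak * (np.exp(-tt[m] / decay_s) - np.exp(-tt[m] / rise_s))
    return env


def simulate_ensemble(model: EnsembleModel, sample_rate: float = 10_000.0
                      ) -> list[tuple[VoltageTrace, SpikeTrain]]:
    """Simulate a bursting ensemble; reproducible from ``model.seed``.

    Random streams are derived from the single model seed with
    ``numpy.random.SeedSequence.spawn`` in a fixed order (burst process,
    then per-cell jitter/background/noise), so identical models replay
    bit-identically.
    """
    _check_rate(sample_rate, 1000.0)
    ss = np.random.SeedSequence(model.seed)
    burst_ss, *cell_ss = ss.spawn(1 + model.n_cells)
    rng = np.random.default_rng(burst_ss)

    dur = model.duration_s
    expected_bursts = model.burst_rate_Hz * dur
    if 0 < expected_bursts < 1:
        warnings.warn("duration too short to contain one expected burst",
                      stacklevel=2)
    n_bursts = rng.poisson(expected_bursts) if model.burst_rate_Hz > 0 else 0
    burst_onsets = np.sort(rng.uniform(0, dur, size=n_bursts))
    # shared within-burst template spike times
    template = [on + np.arange(model.spikes_per_burst)
                * model.intra_burst_interval_ms / 1000.0
                for on in burst_onsets]
    template_times = np.concatenate(template) if template else np.empty(0)

    n_total = int(round(dur * sample_rate))
    t = np.arange(n_total) / sample_rate
    cell = CellMembraneModel()
    common_env = _alpha_envelope(t, burst_onsets, model.subthreshold_common_amp_mV)

    out = []
    min_isi = 2e-3  # enforce a refractory floor on the merged train
    for c in range(model.n_cells):
        crng = np.random.default_rng(cell_ss[c])
        jitter = crng.normal(0.0, model.sync_jitter_ms / 1000.0,
                             size=template_times.size)
        burst_spikes = template_times + jitter
        n_bg = crng.poisson(model.independent_rate_Hz * dur)
        bg = crng.uniform(0, dur, size=n_bg)
        all_sp = np.sort(np.concatenate([burst_spikes, bg]))
        all_sp = all_sp[(all_sp >= 0) & (all_sp < dur - 1.0 / sample_rate)]
        keep = []
        for s in all_sp:
            if not keep or s - keep[-1] >= min_isi:
                keep.append(s)
        sp = np.asarray(keep)
        v = (cell.resting_mV + common_env
             + crng.normal(0.0, model.subthreshold_noise_mV, size=n_total))
        _stamp_spikes(v, sp, cell, sample_rate)
        out.append((VoltageTrace(times=t, values=v, sample_rate=sample_rate),
                    SpikeTrain(times=sp, duration_s=dur, source=f"cell{c}")))
    return out
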
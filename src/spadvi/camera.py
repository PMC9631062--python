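"""Forward model from membrane voltage to binary SPAD bit planes.

Voltage couples linearly into relative GEVI fluorescence with first-order
indicator kinetics; fluorescence scales a per-pixel photon rate map over a
membrane-annulus footprint; each exposure of each pixel then reports 1
with probability ``1 - exp(-lambda)`` (at least one Poisson photon or dark
event during the exposure), independently across pixels and planes.

A global shutter is assumed: all pixels share each exposure window, and
fluorescence is sample-and-held from the voltage grid at the exposure
start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neuron import VoltageTrace

__all__ = [
    "IndicatorModel",
    "SensorModel",
    "CellFootprint",
    "BitPlaneStack",
    "voltage_to_fluorescence",
    "render_photon_rates",
    "sample_bit_planes",
]


@dataclass(frozen=True)
class IndicatorModel:
    """Linear voltage-to-fluorescence indicator with first-order kinetics.

    Attributes
    ----------
    coupling_per_mV : float
        Fractional fluorescence change per mV of depolarization (signed;
        Voltron-like indicators dim on depolarization, i.e., negative).
    kinetics_tau_ms : float
        First-order indicator time constant in ms (0 = instantaneous).
    baseline_brightness : float
        Detected photons/s per unit footprint weight at resting potential
        (detection efficiency applied separately by the sensor model).
    """

    coupling_per_mV: float = -0.001
    kinetics_tau_ms: float = 0.5
    baseline_brightness: float = 5.0e3

    def __post_init__(self):
        if self.kinetics_tau_ms < 0:
            raise ValueError("kinetics_tau_ms must be >= 0")
        if self.baseline_brightness <= 0:
            raise ValueError("baseline_brightness must be positive")


@dataclass(frozen=True)
class SensorModel:
    """Binary SPAD array geometry and rates (SPCImager-like defaults)."""

    width: int = 320
    height: int = 240
    pixel_pitch_um: float = 8.0
    frame_rate_Hz: float = 9938.4
    dark_count_rate_cps: float = 100.0
    detection_efficiency: float = 1.0

    def __post_init__(self):
        if self.frame_rate_Hz <= 0:
            raise ValueError("frame_rate_Hz must be positive")
        if self.dark_count_rate_cps < 0:
            raise ValueError("dark_count_rate_cps must be >= 0")
        if not (0 < self.detection_efficiency <= 1):
            raise ValueError("detection_efficiency must be in (0, 1]")

    @property
    def exposure_s(self) -> float:
        return 1.0 / self.frame_rate_Hz


@dataclass(frozen=True)
class CellFootprint:
    """Somatic footprint: bright membrane annulus, dim interior.

    ``weight_map`` is a (height, width) array of nonnegative per-pixel
    weights; background pixels are 0.
    """

    center_px: tuple
    soma_radius_px: float
    annulus_width_px: float
    weight_map: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weight_map, dtype=float)
        if np.any(w < 0):
            raise ValueError("footprint weights must be >= 0")
        object.__setattr__(self, "weight_map", w)

    @classmethod
    def soma_annulus(cls, shape: tuple, center_px: tuple,
                     soma_radius_px: float = 12.0, annulus_width_px: float = 3.0,
                     annulus_weight: float = 1.0, interior_weight: float = 0.2
                     ) -> "CellFootprint":
        """Disk footprint with the indicator concentrated on the membrane."""
        if interior_weight >= annulus_weight:
            raise ValueError("annulus must be brighter than the interior")
        h, w = shape
        rr, cc = np.ogrid[:h, :w]
        r = np.hypot(rr - center_px[0], cc - center_px[1])
        wm = np.zeros(shape, dtype=float)
        wm[r < soma_radius_px] = interior_weight
        wm[(r >= soma_radius_px - annulus_width_px) & (r < soma_radius_px)] = annulus_weight
        return cls(center_px=tuple(center_px), soma_radius_px=soma_radius_px,
                   annulus_width_px=annulus_width_px, weight_map=wm)

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.weight_map))

    def mask(self) -> np.ndarray:
        return self.weight_map > 0


@dataclass
class BitPlaneStack:
    """A stack of binary frames plus acquisition metadata.

    ``planes`` is a (n_planes, height, width) uint8 array of {0, 1}.
    """

    planes: np.ndarray
    frame_rate_Hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.planes)
        if p.ndim != 3 or p.shape[0] < 1:
            raise ValueError("planes must be (n_planes, height, width), n_planes >= 1")
        if not np.isin(p, (0, 1)).all():
            raise ValueError("bit-plane values must be 0 or 1")
        self.planes = p.astype(np.uint8)

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def height(self) -> int:
        return self.planes.shape[1]

    @property
    def width(self) -> int:
        return self.planes.shape[2]

    def __eq__(self, other) -> bool:
        return (isinstance(other, BitPlaneStack)
                and self.planes.shape == other.planes.shape
                and np.array_equal(self.planes, other.planes)
                and self.frame_rate_Hz == other.frame_rate_Hz
                and self.metadata == other.metadata)


def voltage_to_fluorescence(v: VoltageTrace, indicator: IndicatorModel,
                            v_rest_mV: float | None = None,
                            floor_eps: float = 1e-6) -> np.ndarray:
    """Relative fluorescence ``F_rel(t)`` for a voltage trace.

    ``F_rel = 1 + coupling_per_mV * (V - V_rest)`` followed by a
    first-order low-pass with the indicator time constant (identity when
    the constant is 0). Output is strictly positive: values driven to or
    below 0 by a large coupling are floored at ``floor_eps`` with a
    warning.
    """
    v_rest = float(v.values[0]) if v_rest_mV is None else float(v_rest_mV)
    f = 1.0 + indicator.coupling_per_mV * (v.values - v_rest)
    if indicator.kinetics_tau_ms > 0:
        dt_ms = 1000.0 / v.sample_rate
        alpha = 1.0 - np.exp(-dt_ms / indicator.kinetics_tau_ms)
        from scipy.signal import lfilter, lfiltic
        # y[i] = y[i-1] + alpha * (x[i] - y[i-1]), y[-1] = x[0]
        b, a = [alpha], [1.0, -(1.0 - alpha)]
        zi = lfiltic(b, a, [f[0]], [f[0]])
        f, _ = lfilter(b, a, f, zi=zi)
    if np.any(f <= 0):
        warnings.warn("relative fluorescence floored at epsilon "
                      "(coupling drives F_rel <= 0)", stacklevel=2)
        f = np.maximum(f, floor_eps)
    return f


def _resample_hold(f_rel: np.ndarray, source_rate: float, sensor_rate: float,
                   n_frames: int) -> np.ndarray:
    """Sample-and-hold f_rel (on the voltage grid) at exposure starts."""
    if source_rate < sensor_rate * (1 - 1e-9):
        raise ValueError("voltage grid must be at least as fast as the sensor")
    idx = np.floor(np.arange(n_frames) / sensor_rate * source_rate).astype(int)
    idx = np.minimum(idx, f_rel.size - 1)
    return f_rel[idx]


def render_photon_rates(f_rel: np.ndarray, footprint: CellFootprint,
                        indicator: IndicatorModel, sensor: SensorModel,
                        source_rate_Hz: float | None = None,
                        n_frames: int | None = None) -> np.ndarray:
    """Per-pixel expected photons per exposure, shape (n_frames, h, w).

    ``lambda(x, t) = eff * brightness * weight(x) * F_rel(t) * exposure
    + dark_rate * exposure``.

    If ``source_rate_Hz`` is given, ``f_rel`` (on the voltage grid) is
    sample-and-held onto the sensor frame grid first; otherwise it is
    taken to be on the frame grid already.
    """
    f_rel = np.asarray(f_rel, dtype=float)
    if source_rate_Hz is not None:
        if n_frames is None:
            n_frames = int(np.floor(f_rel.size * sensor.frame_rate_Hz / source_rate_Hz))
        f_rel = _resample_hold(f_rel, source_rate_Hz, sensor.frame_rate_Hz, n_frames)
    exp_s = sensor.exposure_s
    signal = (sensor.detection_efficiency * indicator.baseline_brightness * exp_s
              * footprint.weight_map[None, :, :] * f_rel[:, None, None])
    return signal + sensor.dark_count_rate_cps * exp_s


def sample_bit_planes(rates: np.ndarray, seed, frame_rate_Hz: float,
                      metadata: dict | None = None) -> BitPlaneStack:
    """Draw a binary stack from expected-photon rates.

    Each pixel/plane is an independent Bernoulli draw with
    ``p = 1 - exp(-lambda)``; fully reproducible from ``seed`` (an int or
    a ``numpy.random.Generator``).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("photon rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = -np.expm1(-rates)
    planes = (rng.random(rates.shape) < p).astype(np.uint8)
    return BitPlaneStack(planes=planes, frame_rate_Hz=frame_rate_Hz,
                         metadata=dict(metadata or {}))
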
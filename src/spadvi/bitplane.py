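"""Bit-plane container I/O, image composition, and pixel-response correction.

The native container is ``.spb``, a packed-bit format with a 32-byte
little-endian header::

    magic "SPB1" (4s) | version u8 | reserved 3B | width u16 | height u16 |
    n_planes u32 | frame_rate_Hz f64 | flags u32 | metadata_len u32

followed by ``metadata_len`` bytes of UTF-8 JSON, then the planes in time
order, each plane row-major with bits packed MSB-first and padded to a
byte boundary. Multipage TIFF (1-bit or 8-bit) is supported as the
interchange path.

Composed images are per-pixel sums of binary planes; ``correct_image``
inverts the binary pixel's logarithmic (saturating) response via
``lambda = -ln(1 - p)`` and subtracts the expected dark-count term.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np

from .camera import BitPlaneStack, SensorModel

__all__ = [
    "ComposedImage",
    "write_stack",
    "read_stack",
    "write_tiff",
    "read_tiff",
    "compose_image",
    "correct_image",
    "FormatError",
]

_MAGIC = b"SPB1"
_VERSION = 1
_HEADER = struct.Struct("<4sB3sHHIdII")
assert _HEADER.size == 32


class FormatError(ValueError):
    """Raised when an .spb file is malformed (bad magic/version/truncation)."""


@dataclass
class ComposedImage:
    """Per-pixel summed counts (or corrected intensities) over N planes."""

    values: np.ndarray
    n_planes_summed: int
    corrected: dict = field(default_factory=lambda: {"dark": False, "log": False})

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("composed image must be 2-D")
        if not any(self.corrected.values()):
            if np.any((v < 0) | (v > self.n_planes_summed)):
                raise ValueError("raw sums must lie in [0, n_planes_summed]")
        elif np.any(v < 0):
            raise ValueError("corrected intensities must be >= 0")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")

    def to_tiff(self, path) -> None:
        import tifffile
        v = self.values
        arr = v.astype(np.uint16) if not any(self.corrected.values()) \
            else v.astype(np.float32)
        tifffile.imwrite(path, arr)


def write_stack(stack: BitPlaneStack, path) -> None:
    """Serialize a stack to .spb; ``read_stack(write_stack(s)) == s``."""
    meta = json.dumps(stack.metadata).encode("utf-8") if stack.metadata else b""
    header = _HEADER.pack(_MAGIC, _VERSION, b"\x00" * 3,
                          stack.width, stack.height, stack.n_planes,
                          stack.frame_rate_Hz, 0, len(meta))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(meta)
        for plane in stack.planes:
            fh.write(np.packbits(plane.ravel()).tobytes())


def read_stack(path) -> BitPlaneStack:
    """Read an .spb file, validating magic, version and payload length."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size:
        raise FormatError(f"truncated header: {len(raw)} bytes at offset 0, "
                          f"expected {_HEADER.size}")
    magic, version, _, width, height, n_planes, rate, _flags, meta_len = \
        _HEADER.unpack_from(raw, 0)
    if magic != _MAGIC:
        raise FormatError(f"bad magic {magic!r} at offset 0")
    if version != _VERSION:
        raise FormatError(f"unsupported version {version} at offset 4")
    off = _HEADER.size
    if len(raw) < off + meta_len:
        raise FormatError(f"truncated metadata at offset {off}")
    metadata = json.loads(raw[off:off + meta_len]) if meta_len else {}
    off += meta_len
    plane_bytes = (width * height + 7) // 8
    expected = off + plane_bytes * n_planes
    if len(raw) < expected:
        raise FormatError(f"truncated plane data at offset {len(raw)}, "
                          f"expected {expected} bytes")
    planes = np.empty((n_planes, height, width), dtype=np.uint8)
    for i in range(n_planes):
        bits = np.unpackbits(np.frombuffer(raw, np.uint8, plane_bytes,
                                           off + i * plane_bytes))
        planes[i] = bits[:width * height].reshape(height, width)
    return BitPlaneStack(planes=planes, frame_rate_Hz=rate, metadata=metadata)


def write_tiff(stack: BitPlaneStack, path) -> None:
    """Export as 8-bit multipage TIFF (values 0/1)."""
    import tifffile
    tifffile.imwrite(path, stack.planes, photometric="minisblack")


def read_tiff(path, frame_rate_Hz: float, metadata: dict | None = None
              ) -> BitPlaneStack:
    """Import a 1-bit or 8-bit multipage TIFF; nonzero pixels become 1."""
    import tifffile
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    planes = (arr != 0).astype(np.uint8)
    return BitPlaneStack(planes=planes, frame_rate_Hz=frame_rate_Hz,
                         metadata=dict(metadata or {}))


def compose_image(stack: BitPlaneStack, plane_range: tuple | None = None
                  ) -> ComposedImage:
    """Sum binary planes over a half-open interval into one image."""
    lo, hi = (0, stack.n_planes) if plane_range is None else plane_range
    if not (0 <= lo < hi <= stack.n_planes):
        raise ValueError(f"empty or out-of-range plane interval [{lo}, {hi}) "
                         f"for a stack of {stack.n_planes} planes")
    values = stack.planes[lo:hi].sum(axis=0, dtype=np.int64)
    return ComposedImage(values=values, n_planes_summed=hi - lo)


def correct_image(img: ComposedImage, sensor: SensorModel,
                  dark_map: np.ndarray | None = None) -> ComposedImage:
    """Invert the binary pixel response and subtract dark counts.

    Occupancy ``p = sum / n`` maps back to expected photons per exposure
    via ``lambda = -ln(1 - p)``; fully saturated pixels (p = 1) are capped
    at ``-ln(1 / (2n))`` to keep statistics finite. The expected dark term
    ``dark_count_rate * exposure`` (or a per-pixel ``dark_map`` of
    events/exposure) is then subtracted and the result clipped at 0.
    """
    if any(img.corrected.values()):
        raise ValueError("image is already corrected")
    n = img.n_planes_summed
    if n == 0:
        raise ValueError("n_planes_summed must be positive")
    p = img.values / n
    p = np.minimum(p, 1.0 - 1.0 / (2 * n))
    lam = -np.log1p(-p)
    dark = (sensor.dark_count_rate_cps * sensor.exposure_s
            if dark_map is None else np.asarray(dark_map, dtype=float))
    out = np.clip(lam - dark, 0.0, None)
    return ComposedImage(values=out, n_planes_summed=n,
                         corrected={"dark": True, "log": True})
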
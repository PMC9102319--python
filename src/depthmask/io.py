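"""Depth-video containers, mask files, point conversion and chunk planning.

The on-disk depth container (``.dvs``) is a fixed little-endian layout:

========  =====  ==========================================================
offset    size   field
========  =====  ==========================================================
0         4      magic ``b"DVSM"``
4         4      u32 version (currently 1)
8         4      u32 width
12        4      u32 height
16        4      u32 frame_count
20        4      u32 frame rate in millihertz (30000 = 30 fps)
24        1      u8 sample dtype: 0 = u16, 1 = f32
25        3      reserved (zero)
28        ...    frame_count row-major frames of width*height samples
========  =====  ==========================================================

Masks are written as binary (P5) PGM files with samples in {0, 255}.  A
depth value of 0 always means an invalid ("hole") pixel and never produces
a 3D point.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, CorruptionError, FormatError

MAGIC = b"DVSM"
VERSION = 1
_HEADER = struct.Struct("<4sIIIIIB3x")

_DTYPE_CODES = {0: np.dtype("<u2"), 1: np.dtype("<f4")}
_DTYPE_FOR = {np.dtype("<u2"): 0, np.dtype("<f4"): 1}


class Point3D:
    """A 3D point lifted from a depth pixel.

    ``x, y, z`` are world coordinates (pixel column/row and depth times the
    conversion scales); ``px, py`` remember the source pixel.
    """

    __slots__ = ("x", "y", "z", "px", "py")

    def __init__(self, x: float, y: float, z: float, px: int, py: int):
        self.x = x
        self.y = y
        self.z = z
        self.px = px
        self.py = py

    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def pixel(self) -> tuple[int, int]:
        return (self.px, self.py)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Point3D({self.x}, {self.y}, {self.z}, px={self.px}, py={self.py})"


@dataclass
class DepthFrame:
    """One depth image: a ``height x width`` grid of non-negative depths."""

    values: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ContractError("DepthFrame.values must be a non-empty 2D array")
        if np.any(np.asarray(self.values, dtype=float) < 0):
            raise ContractError("depth values must be >= 0")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]


@dataclass
class DepthSequence:
    """An ordered list of equally sized depth frames."""

    frames: list[DepthFrame]
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ContractError("DepthSequence needs at least one frame")
        w, h = self.frames[0].width, self.frames[0].height
        for f in self.frames:
            if (f.width, f.height) != (w, h):
                raise ContractError("all frames must share dimensions")

    @property
    def width(self) -> int:
        return self.frames[0].width

    @property
    def height(self) -> int:
        return self.frames[0].height

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MaskFrame:
    """A binary mask aligned with a depth frame (1 = object)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ContractError("MaskFrame.bits must be 2D")
        if not np.isin(self.bits, (0, 1)).all():
            raise ContractError("mask entries must be 0 or 1")

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    @property
    def height(self) -> int:
        return self.bits.shape[0]

    def pixel_set(self) -> set[tuple[int, int]]:
        ys, xs = np.nonzero(self.bits)
        return set(zip(xs.tolist(), ys.tolist()))

    @classmethod
    def from_pixels(cls, width: int, height: int,
                    pixels: Iterable[tuple[int, int]]) -> "MaskFrame":
        bits = np.zeros((height, width), dtype=np.uint8)
        for px, py in pixels:
            bits[py, px] = 1
        return cls(bits)


@dataclass
class ChunkPlan:
    """A partition of ``[0, total_frames)`` into contiguous windows."""

    window_frames: int
    total_frames: int
    windows: list[tuple[int, int]] = field(default_factory=list)


def _coerce_dtype(seq: DepthSequence) -> np.dtype:
    for f in seq.frames:
        if np.issubdtype(f.values.dtype, np.floating):
            return np.dtype("<f4")
    return np.dtype("<u2")


def write_sequence(seq: DepthSequence, path: str | Path,
                   dtype: str | None = None) -> Path:
    """Serialize a sequence to the DVS container.

    ``dtype`` may be ``"u16"`` or ``"f32"``; by default u16 is used unless
    any frame holds floating-point values.  The byte stream is a pure
    function of the sequence, so identical sequences produce identical
    files.
    """
    if dtype is None:
        np_dtype = _coerce_dtype(seq)
    elif dtype == "u16":
        np_dtype = np.dtype("<u2")
    elif dtype == "f32":
        np_dtype = np.dtype("<f4")
    else:
        raise ContractError(f"unknown dtype {dtype!r}")

    path = Path(path)
    millihz = int(round(seq.frame_rate * 1000))
    header = _HEADER.pack(MAGIC, VERSION, seq.width, seq.height,
                          len(seq.frames), millihz, _DTYPE_FOR[np_dtype])
    with open(path, "wb") as fh:
        fh.write(header)
        for frame in seq.frames:
            fh.write(np.ascontiguousarray(frame.values, dtype=np_dtype).tobytes())
    return path


def read_sequence(path: str | Path) -> DepthSequence:
    """Read a DVS container back into a :class:`DepthSequence`."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER.size)
        if len(raw) < _HEADER.size:
            raise FormatError(f"{path}: file shorter than the DVS header")
        magic, version, width, height, count, millihz, code = _HEADER.unpack(raw)
        if magic != MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r}")
        if version != VERSION:
            raise FormatError(f"{path}: unsupported version {version}")
        if code not in _DTYPE_CODES:
            raise FormatError(f"{path}: unknown dtype code {code}")
        np_dtype = _DTYPE_CODES[code]
        frame_bytes = width * height * np_dtype.itemsize
        frames = []
        for i in range(count):
            payload = fh.read(frame_bytes)
            if len(payload) < frame_bytes:
                raise CorruptionError(
                    f"{path}: truncated payload at frame {i} "
                    f"({len(payload)} of {frame_bytes} bytes)")
            values = np.frombuffer(payload, dtype=np_dtype).reshape(height, width)
            frames.append(DepthFrame(values.copy(), index=i))
    return DepthSequence(frames, frame_rate=millihz / 1000.0)


def write_mask_pgm(mask: MaskFrame, path: str | Path) -> Path:
    """Write a mask as a binary PGM: 0 = background, 255 = object."""
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(f"P5\n{mask.width} {mask.height}\n255\n".encode("ascii"))
        fh.write((mask.bits * np.uint8(255)).tobytes())
    return path


def read_mask_pgm(path: str | Path) -> MaskFrame:
    """Read a binary PGM back into a mask (any nonzero sample -> 1)."""
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    parts = data.split(maxsplit=4)
    if len(parts) < 5 or parts[0] != b"P5":
        raise FormatError(f"{path}: not a binary PGM")
    width, height, maxval = int(parts[1]), int(parts[2]), int(parts[3])
    if maxval > 255:
        raise FormatError(f"{path}: 16-bit PGM not supported")
    samples = np.frombuffer(parts[4][: width * height], dtype=np.uint8)
    if samples.size < width * height:
        raise CorruptionError(f"{path}: truncated PGM payload")
    return MaskFrame((samples.reshape(height, width) > 0).astype(np.uint8))


def write_mask_pair(frame: DepthFrame, mask: MaskFrame, out_dir: str | Path,
                    stem: str = "frame") -> tuple[Path, Path]:
    """Write one frame as a single-frame DVS plus its mask as a PGM.

    Files are named ``<stem>_NNNNNN.depth.dvs`` / ``<stem>_NNNNNN.mask.pgm``
    using the frame's zero-padded index, so a sequence of pairs sorts in
    frame order.
    """
    if (frame.width, frame.height) != (mask.width, mask.height):
        raise ContractError("frame and mask dimensions differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = f"{stem}_{frame.index:06d}"
    depth_path = write_sequence(DepthSequence([frame]), out_dir / f"{base}.depth.dvs")
    mask_path = write_mask_pgm(mask, out_dir / f"{base}.mask.pgm")
    return depth_path, mask_path


def frame_to_points(frame: DepthFrame,
                    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
                    ) -> list[Point3D]:
    """Lift every valid (depth > 0) pixel to a 3D point, row-major order.

    World coordinates are ``(px*sx, py*sy, depth*sz)`` — with unit scales
    the cloud lives in pixel/depth-value units, which is also the unit of
    the clustering margin ``b``.
    """
    sx, sy, sz = scale
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ContractError("scales must be positive")
    vals = np.asarray(frame.values, dtype=float)
    ys, xs = np.nonzero(vals > 0)
    depths = vals[ys, xs]
    return [Point3D(px * sx, py * sy, d * sz, int(px), int(py))
            for px, py, d in zip(xs.tolist(), ys.tolist(), depths.tolist())]


def plan_chunks(total_frames: int, window_frames: int) -> ChunkPlan:
    """Split ``total_frames`` into contiguous windows of at most
    ``window_frames`` frames (the last window may be short)."""
    if total_frames < 1 or window_frames < 1:
        raise ContractError("frame counts must be >= 1")
    windows = [(s, min(s + window_frames, total_frames))
               for s in range(0, total_frames, window_frames)]
    return ChunkPlan(window_frames=window_frames, total_frames=total_frames,
                     windows=windows)


@dataclass(frozen=True)
class MemoryModel:
    """Per-point memory accounting of the kd-tree cloud representation.

    Each point stores three 8-byte coordinates, two 4-byte pixel indices
    and an 8-byte reference to the point (the payload); the tree node adds
    two 8-byte child references, two 1-byte flags (removed and
    subtree-active) and a 4-byte split-dimension integer.
    """

    payload_bytes_per_point: int = 3 * 8 + 2 * 4 + 2 * 8
    total_bytes_per_point: int = 3 * 8 + 2 * 4 + 2 * 8 + 2 * 8 + 1 + 1 + 4

    def bytes_for(self, points: int) -> int:
        if points < 0:
            raise ContractError("point count must be >= 0")
        return points * self.total_bytes_per_point


def memory_model(points_per_frame: int = 0) -> MemoryModel:
    """Return the per-point memory accounting record."""
    if points_per_frame < 0:
        raise ContractError("point count must be >= 0")
    return MemoryModel()
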
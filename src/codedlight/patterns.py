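"""Binary coded-light pattern generation and decoding.

A structured-light projector encodes its pixel coordinates with a temporal
sequence of binary stripe patterns: a reflected-binary Gray code gives a
robust coarse stripe index, and a sliding narrow-line sequence (here called
the phase-shift sequence, after the commercial usage for binary line codes)
refines the coordinate to single-pixel precision.  A camera watching the
illuminated scene sees, at every pixel, a bit vector that identifies the
projector pixel whose light it receives; decoding that vector removes the
stereo correspondence problem entirely.

With the defaults (8 Gray levels per axis, 16-pixel shift period, 1-pixel
lines) the sequence is 2*8 + 2*16 = 48 frames: 16 Gray-code frames followed
by 32 phase-shift frames, horizontal axis before vertical within each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

Axis = Literal["horizontal", "vertical"]
Kind = Literal["gray", "phase_shift"]

__all__ = [
    "PatternSpec",
    "FrameMeta",
    "PatternSequence",
    "PixelCodeMap",
    "CodedCaptureSet",
    "generate_gray_patterns",
    "generate_phase_shift_patterns",
    "full_sequence",
    "binarize_captures",
    "decode_projector_coords",
    "gray_encode",
    "gray_decode",
]


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of the projected code.

    Parameters
    ----------
    width, height:
        Projector resolution in pixels.
    gray_levels:
        Number of Gray-code bit planes per axis; the axis is quantized into
        ``2**gray_levels`` stripes of near-equal integer width.
    shift_period:
        Period of the sliding-line sequence in pixels; one frame per shift.
    line_width:
        Width of the lit line in each phase-shift frame.
    """

    width: int = 1024
    height: int = 768
    gray_levels: int = 8
    shift_period: int = 16
    line_width: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("pattern dimensions must be positive")
        if self.gray_levels < 1:
            raise ValueError("gray_levels must be >= 1")
        if not (self.shift_period > self.line_width >= 1):
            raise ValueError("require shift_period > line_width >= 1")

    @property
    def frame_count(self) -> int:
        """Total frames in the full sequence (2*levels + 2*period)."""
        return 2 * self.gray_levels + 2 * self.shift_period

    def axis_size(self, axis: Axis) -> int:
        if axis == "horizontal":
            return self.width
        if axis == "vertical":
            return self.height
        raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class FrameMeta:
    kind: Kind
    axis: Axis
    index: int


@dataclass
class PatternSequence:
    """Ordered stack of binary projector frames with per-frame metadata."""

    spec: PatternSpec
    frames: list[np.ndarray]
    meta: list[FrameMeta]

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        return np.stack(self.frames).astype(np.uint8)


@dataclass
class PixelCodeMap:
    """Per-camera-pixel decoding result.

    ``u``/``v`` hold decoded projector coordinates (``-1`` where invalid);
    ``valid_mask`` marks pixels with a consistent, in-range code.
    """

    bits: np.ndarray  # (n_frames, H, W) uint8
    valid_mask: np.ndarray  # (H, W) bool
    u: np.ndarray  # (H, W) int32 projector column, -1 invalid
    v: np.ndarray  # (H, W) int32 projector row, -1 invalid

    @property
    def projector_coords(self) -> np.ndarray:
        """(H, W, 2) array of (u, v); -1 where invalid."""
        return np.stack([self.u, self.v], axis=-1)


@dataclass
class CodedCaptureSet:
    """One viewpoint's captures: full-light RGB, references, coded frames."""

    rgb: np.ndarray  # (H, W, 3) uint8 full-light photograph
    lit_reference: np.ndarray  # (H, W) float, all-white pattern
    dark_reference: np.ndarray  # (H, W) float, all-black pattern
    frames: np.ndarray  # (n_frames, H, W) float, canonical order
    spec: PatternSpec
    view_deg: float = 0.0


def gray_encode(n: np.ndarray | int) -> np.ndarray | int:
    """Reflected-binary Gray code of ``n``."""
    n = np.asarray(n)
    return n ^ (n >> 1)


def gray_decode(g: np.ndarray | int, bits: int = 16) -> np.ndarray:
    """Inverse of :func:`gray_encode` for values below ``2**bits``."""
    b = np.array(g, copy=True)
    shift = 1
    while shift < bits:
        b ^= b >> shift
        shift *= 2
    return b


def _stripe_index(size: int, levels: int) -> np.ndarray:
    # Quantize coordinates into 2**levels stripes of near-equal integer
    # width (size need not be divisible by 2**levels).
    coords = np.arange(size, dtype=np.int64)
    return (coords * (1 << levels)) // size


def generate_gray_patterns(spec: PatternSpec, axis: Axis) -> list[np.ndarray]:
    """Gray-code bit-plane images for one axis, coarsest (MSB) first.

    Frame ``k`` (0-based) shows bit ``levels-1-k`` of the Gray code of the
    coordinate's stripe index, so the first frame is half light, half dark.
    """
    size = spec.axis_size(axis)
    levels = spec.gray_levels
    codes = gray_encode(_stripe_index(size, levels))
    frames = []
    for k in range(levels):
        bitplane = ((codes >> (levels - 1 - k)) & 1).astype(np.uint8)
        frames.append(_stripe_image(bitplane, spec, axis))
    return frames


def generate_phase_shift_patterns(spec: PatternSpec, axis: Axis) -> list[np.ndarray]:
    """Sliding-line frames: frame ``s`` lights coordinates with
    ``(coord - s) mod shift_period < line_width``."""
    size = spec.axis_size(axis)
    coords = np.arange(size, dtype=np.int64)
    frames = []
    for s in range(spec.shift_period):
        line = (((coords - s) % spec.shift_period) < spec.line_width).astype(np.uint8)
        frames.append(_stripe_image(line, spec, axis))
    return frames


def _stripe_image(profile: np.ndarray, spec: PatternSpec, axis: Axis) -> np.ndarray:
    if axis == "horizontal":
        return np.broadcast_to(profile[np.newaxis, :], (spec.height, spec.width)).copy()
    return np.broadcast_to(profile[:, np.newaxis], (spec.height, spec.width)).copy()


def full_sequence(spec: PatternSpec) -> PatternSequence:
    """The canonical 48-frame sequence: Gray (h, v) then phase shift (h, v)."""
    frames: list[np.ndarray] = []
    meta: list[FrameMeta] = []
    for axis in ("horizontal", "vertical"):
        for i, frame in enumerate(generate_gray_patterns(spec, axis)):
            frames.append(frame)
            meta.append(FrameMeta("gray", axis, i))
    for axis in ("horizontal", "vertical"):
        for i, frame in enumerate(generate_phase_shift_patterns(spec, axis)):
            frames.append(frame)
            meta.append(FrameMeta("phase_shift", axis, i))
    return PatternSequence(spec, frames, meta)


def _dynamic_range(img: np.ndarray) -> float:
    if np.issubdtype(img.dtype, np.integer):
        return float(np.iinfo(img.dtype).max)
    return 1.0


def binarize_captures(
    captures: Sequence[np.ndarray] | np.ndarray,
    lit_reference: np.ndarray,
    dark_reference: np.ndarray,
    contrast_floor: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold coded captures against per-pixel lit/dark references.

    The threshold at each pixel is the midpoint of the lit and dark
    reference intensities.  Pixels whose lit-dark contrast falls below
    ``contrast_floor`` (a fraction of the image dynamic range) are flagged
    unreliable — typically background or projector-shadowed surface.

    Returns
    -------
    bits : (n_frames, H, W) uint8
    reliable : (H, W) bool
    """
    stack = np.asarray(captures, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("captures must be a stack of 2-D grayscale images")
    lit = np.asarray(lit_reference, dtype=np.float64)
    dark = np.asarray(dark_reference, dtype=np.float64)
    if lit.shape != dark.shape or stack.shape[1:] != lit.shape:
        raise ValueError(
            "capture set misaligned: frames "
            f"{stack.shape[1:]} vs references {lit.shape}/{dark.shape}"
        )
    rng = _dynamic_range(np.asarray(lit_reference))
    threshold = 0.5 * (lit + dark)
    bits = (stack > threshold[np.newaxis]).astype(np.uint8)
    reliable = (lit - dark) >= contrast_floor * rng
    return bits, reliable


def _decode_axis(
    gray_bits: np.ndarray,
    phase_bits: np.ndarray,
    size: int,
    spec: PatternSpec,
    max_lit_frames: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Decode one axis: Gray stripe index fused with the phase residue."""
    levels = spec.gray_levels
    period = spec.shift_period
    w = spec.line_width

    # Coarse: Gray bits, MSB first, -> stripe index -> stripe-center coord.
    code = np.zeros(gray_bits.shape[1:], dtype=np.int64)
    for k in range(levels):
        code = (code << 1) | gray_bits[k].astype(np.int64)
    stripe = gray_decode(code, bits=levels)
    coarse = (stripe + 0.5) * (size / (1 << levels))

    # Fine: which phase frame(s) light the pixel.  For line_width w the lit
    # frames for residue r are the circular run {r-w+1 .. r}; accept runs of
    # 1..max_lit_frames consecutive frames and take the run's end.
    lit_count = phase_bits.sum(axis=0).astype(np.int64)
    ok = (lit_count >= 1) & (lit_count <= max_lit_frames)

    mask_word = np.zeros(phase_bits.shape[1:], dtype=np.int64)
    for s in range(period):
        mask_word |= phase_bits[s].astype(np.int64) << s

    residue = np.full(phase_bits.shape[1:], -1, dtype=np.int64)
    matched = np.zeros(phase_bits.shape[1:], dtype=bool)
    for r in range(period):
        for n in range(1, max_lit_frames + 1):
            expect = 0
            for j in range(n):
                expect |= 1 << ((r - j) % period)
            hit = (mask_word == expect) & ~matched
            if np.any(hit):
                residue[hit] = r
                matched |= hit
    ok &= matched

    # Fuse: nearest coordinate consistent with the residue modulo period.
    fused = residue + period * np.rint((coarse - residue) / period).astype(np.int64)
    ok &= np.abs(fused - coarse) <= period / 2 + 0.5
    ok &= (fused >= 0) & (fused < size)
    fused = np.where(ok, fused, -1)
    return fused.astype(np.int32), ok


def decode_projector_coords(
    bitplanes: Sequence[np.ndarray] | np.ndarray,
    spec: PatternSpec,
    mask: np.ndarray,
    max_lit_frames: int | None = None,
) -> PixelCodeMap:
    """Decode a binarized capture stack into projector coordinates.

    ``bitplanes`` must follow the canonical :func:`full_sequence` order.
    ``mask`` marks the pixels to decode (plant pixels with reliable
    contrast); all others are invalid in the result.
    """
    bits = np.asarray(bitplanes, dtype=np.uint8)
    if bits.shape[0] != spec.frame_count:
        raise ValueError(
            f"expected {spec.frame_count} bitplanes, got {bits.shape[0]}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bits.shape[1:]:
        raise ValueError("mask shape does not match bitplanes")
    if max_lit_frames is None:
        max_lit_frames = spec.line_width

    L, P = spec.gray_levels, spec.shift_period
    u, ok_u = _decode_axis(bits[:L], bits[2 * L : 2 * L + P], spec.width, spec, max_lit_frames)
    v, ok_v = _decode_axis(bits[L : 2 * L], bits[2 * L + P :], spec.height, spec, max_lit_frames)
    valid = mask & ok_u & ok_v
    u = np.where(valid, u, -1).astype(np.int32)
    v = np.where(valid, v, -1).astype(np.int32)
    return PixelCodeMap(bits=bits, valid_mask=valid, u=u, v=v)
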
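"""Motion detection by pixel-signature classification.

The imaging pipeline segments every frame with a fixed grey threshold of 33
(possible because active lighting holds the background near grey 48), aligns
the 30-frame stack, and classifies each pixel by the temporal signature of its
binary values: all black -> constant dark, all white -> constant white,
otherwise the number of black/white transitions separates sensor noise (high
switching frequency) from genuine worm motion (few transitions).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from skimage.registration import phase_cross_correlation

from .config import GREY_THRESHOLD

__all__ = [
    "PixelClass",
    "DetectParams",
    "ImageSequence",
    "PixelSignatureMap",
    "segment_frame",
    "align_sequence",
    "classify_pixels",
    "motion_area",
]


class PixelClass(IntEnum):
    CONSTANT_DARK = 0
    CONSTANT_WHITE = 1
    NOISY = 2
    MOTION = 3


@dataclass
class DetectParams:
    """Tunable parameters of the detection stage.

    ``grey_threshold`` is the fixed segmentation level (<= is black).
    ``noise_transition_cutoff`` is the number of black/white transitions per
    stack at or above which a changing pixel is called noise rather than
    motion; the machine only fixes that noise switches more often than motion,
    so the cutoff (default 8 per 30 frames) is explicit and configurable.
    """

    grey_threshold: int = GREY_THRESHOLD
    noise_transition_cutoff: int = 8
    alignment: str = "translation"  # or "none"
    max_shift: int = 10  # search window (px) for translation alignment

    def __post_init__(self) -> None:
        if not 0 < self.grey_threshold < 255:
            raise ValueError("grey_threshold must be in (0, 255)")
        if self.noise_transition_cutoff < 2:
            raise ValueError("noise_transition_cutoff must be >= 2")
        if self.alignment not in ("none", "translation"):
            raise ValueError(f"unknown alignment mode {self.alignment!r}")


@dataclass
class ImageSequence:
    """One day's frame stack for one plate, tagged with the capture phase."""

    frames: np.ndarray  # (T, H, W) uint8
    plate: int = 0
    day: int = 0
    phase: str = "before"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("an image sequence needs >= 2 frames of equal shape")


@dataclass
class PixelSignatureMap:
    """Per-pixel temporal class and transition count for one sequence."""

    classes: np.ndarray  # (H, W) uint8, values of PixelClass
    transitions: np.ndarray  # (H, W) int

    def class_counts(self) -> dict[str, int]:
        return {c.name.lower(): int((self.classes == c).sum()) for c in PixelClass}

    @property
    def motion_mask(self) -> np.ndarray:
        return self.classes == PixelClass.MOTION

    @property
    def noisy_mask(self) -> np.ndarray:
        return self.classes == PixelClass.NOISY


def segment_frame(frame: np.ndarray, params: DetectParams | None = None) -> np.ndarray:
    """Fixed-threshold segmentation: True where the pixel is black (<= 33)."""
    params = params or DetectParams()
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise TypeError(f"expected an 8-bit frame, got dtype {frame.dtype}")
    return frame <= params.grey_threshold


def align_sequence(
    seq: ImageSequence, params: DetectParams | None = None
) -> tuple[ImageSequence, np.ndarray]:
    """Translate every frame onto frame 0 by integer-pixel cross-correlation.

    Returns the aligned sequence and the (T, 2) array of shifts applied.
    Blank (constant) frames get zero shift with a warning; shifts are clipped
    to ``params.max_shift``.
    """
    params = params or DetectParams()
    frames = seq.frames
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    if params.alignment == "none":
        return seq, shifts
    ref = frames[0]
    out = frames.copy()
    if ref.std() == 0:
        warnings.warn("blank reference frame; alignment skipped", stacklevel=2)
        return ImageSequence(out, seq.plate, seq.day, seq.phase), shifts
    for i in range(1, frames.shape[0]):
        if frames[i].std() == 0:
            warnings.warn(f"blank frame {i}; zero shift applied", stacklevel=2)
            continue
        shift, _, _ = phase_cross_correlation(
            ref.astype(float), frames[i].astype(float), upsample_factor=1
        )
        dy, dx = (int(round(s)) for s in shift)
        dy = int(np.clip(dy, -params.max_shift, params.max_shift))
        dx = int(np.clip(dx, -params.max_shift, params.max_shift))
        shifts[i] = (dy, dx)
        if dy or dx:
            bg = int(np.bincount(frames[i].ravel()).argmax())
            moved = np.full_like(frames[i], bg)
            h, w = frames[i].shape
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys_src = slice(max(-dy, 0), h + min(-dy, 0))
            xs_src = slice(max(-dx, 0), w + min(-dx, 0))
            moved[ys, xs] = frames[i][ys_src, xs_src]
            out[i] = moved
    return ImageSequence(out, seq.plate, seq.day, seq.phase), shifts


def classify_pixels(
    binary_stack: np.ndarray, params: DetectParams | None = None
) -> PixelSignatureMap:
    """Classify every pixel of an aligned binary stack by its signature.

    All-black -> constant dark; all-white -> constant white; otherwise count
    the black/white transitions along the stack: ``>= noise_transition_cutoff``
    is noise, fewer (but at least one) is motion. The four classes partition
    the image.
    """
    params = params or DetectParams()
    stack = np.asarray(binary_stack, dtype=bool)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) binary stack with T >= 2")
    transitions = (stack[1:] != stack[:-1]).sum(axis=0)
    classes = np.full(stack.shape[1:], PixelClass.MOTION, dtype=np.uint8)
    classes[stack.all(axis=0)] = PixelClass.CONSTANT_DARK
    classes[(~stack).all(axis=0)] = PixelClass.CONSTANT_WHITE
    classes[
        (transitions >= params.noise_transition_cutoff)
        & (classes == PixelClass.MOTION)
    ] = PixelClass.NOISY
    return PixelSignatureMap(classes=classes, transitions=transitions)


def motion_area(sig: PixelSignatureMap, region: np.ndarray | None = None) -> int:
    """Number of motion-class pixels (px^2), optionally within a region mask."""
    motion = sig.motion_mask
    if region is None:
        return int(motion.sum())
    region = np.asarray(region, dtype=bool)
    if region.shape != motion.shape:
        raise ValueError(
            f"region shape {region.shape} does not match map {motion.shape}"
        )
    return int((motion & region).sum())
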
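"""Cycle-normalised video blocks.

A raw echo clip covering one cardiac cycle (arbitrary length and frame size)
is resampled onto a fixed 20-frame grid — 10 frames uniformly spanning
[end-diastole, end-systole) and 10 spanning [end-systole, next end-diastole)
— and each frame is resized to a square raster (256 x 256 by default) with
the native aspect ratio preserved by zero-padding.  Frame selection is
phase-uniform with nearest-source-frame lookup: no temporal blending, so
speckle statistics are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask
from skimage.transform import resize

__all__ = [
    "VIEWS", "N_FRAMES", "FRAME_SIZE", "RawCycle", "VideoBlock", "MaskBlock",
    "select_frame_indices", "resample_cycle", "resample_masks",
    "apply_sector_mask", "resize_frame",
]

VIEWS = ("A4C", "A3C", "A2C")
N_FRAMES = 20
FRAME_SIZE = 256
_HALF = N_FRAMES // 2


@dataclass
class RawCycle:
    """One cardiac cycle of raw frames with annotated ED/ES indices.

    The cycle is assumed to wrap back to the next end-diastole just past the
    last frame; ``next_ed_index`` (default: number of frames) overrides that.
    """

    frames: np.ndarray  # (T, H, W)
    ed_index: int
    es_index: int
    next_ed_index: int | None = None
    sector: np.ndarray | None = None  # (K, 2) polygon vertices, (row, col)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T >= 2, H, W) stack")
        t = self.frames.shape[0]
        if self.next_ed_index is None:
            self.next_ed_index = t
        if not 0 <= self.ed_index < self.es_index:
            raise ValueError(
                f"need 0 <= ED < ES, got ED={self.ed_index}, ES={self.es_index}")
        if not self.es_index < self.next_ed_index <= t:
            raise ValueError("need ES < next ED <= number of frames")


@dataclass
class VideoBlock:
    """Fixed-grid clip: (20, S, S) intensities in [0, 1] plus its view label."""

    data: np.ndarray
    view: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        _check_block_shape(self.data)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")


@dataclass
class MaskBlock:
    """Per-frame label maps {0: background, 1: left myocardium, 2: left ventricle}."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_block_shape(self.data)
        labels = np.unique(self.data)
        if not np.isin(labels, (0, 1, 2)).all():
            raise ValueError(f"mask labels must be within {{0,1,2}}, got {labels}")


def _check_block_shape(data: np.ndarray) -> None:
    if data.ndim != 3 or data.shape[0] != N_FRAMES:
        raise ValueError(f"block must have exactly {N_FRAMES} frames, "
                         f"got shape {data.shape}")
    if data.shape[1] != data.shape[2]:
        raise ValueError(f"block frames must be square, got {data.shape[1:]}")


def select_frame_indices(n_frames: int, ed_index: int, es_index: int,
                         next_ed_index: int | None = None) -> np.ndarray:
    """Source-frame indices for the 20-frame phase grid.

    Ten uniform phases over [ED, ES) and ten over [ES, next ED), each mapped
    to the nearest-from-below source frame; depends only on the index triple,
    never on pixel content.
    """
    if next_ed_index is None:
        next_ed_index = n_frames
    if not 0 <= ed_index < es_index < next_ed_index <= n_frames:
        raise ValueError("need 0 <= ED < ES < next ED <= T")
    k = np.arange(_HALF)
    systole = ed_index + (k * (es_index - ed_index)) // _HALF
    diastole = es_index + (k * (next_ed_index - es_index)) // _HALF
    return np.concatenate([systole, diastole])


def resize_frame(frame: np.ndarray, size: int, order: int = 1) -> np.ndarray:
    """Resize to size x size, isotropic scaling plus centred zero-padding."""
    h, w = frame.shape
    if (h, w) == (size, size):
        return frame.astype(np.float32) if order else frame
    scale = size / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    out = resize(frame.astype(float), (nh, nw), order=order,
                 preserve_range=True, anti_aliasing=(order > 0 and scale < 1))
    pad_t = (size - nh) // 2
    pad_l = (size - nw) // 2
    canvas = np.zeros((size, size), dtype=out.dtype)
    canvas[pad_t:pad_t + nh, pad_l:pad_l + nw] = out
    return canvas


def resample_cycle(raw: RawCycle, view: str = "A4C",
                   size: int = FRAME_SIZE) -> VideoBlock:
    """Resample one cardiac cycle onto the fixed 20 x size x size grid."""
    idx = select_frame_indices(raw.frames.shape[0], raw.ed_index,
                               raw.es_index, raw.next_ed_index)
    frames = raw.frames[idx].astype(np.float32)
    lo, hi = float(frames.min()), float(frames.max())
    if lo < 0.0 or hi > 1.0:  # rescale only when outside [0, 1]
        frames = (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)
    block = np.stack([resize_frame(f, size, order=1) for f in frames])
    return VideoBlock(data=np.clip(block, 0.0, 1.0), view=view)


def resample_masks(raw_masks: np.ndarray, raw: RawCycle,
                   size: int = FRAME_SIZE) -> MaskBlock:
    """Resample annotation masks with the identical index list as the video.

    Spatial resizing is nearest-neighbour so the label set is preserved.
    """
    raw_masks = np.asarray(raw_masks)
    if raw_masks.shape[0] != raw.frames.shape[0]:
        raise ValueError(
            f"mask stack length {raw_masks.shape[0]} does not match "
            f"video length {raw.frames.shape[0]}")
    idx = select_frame_indices(raw.frames.shape[0], raw.ed_index,
                               raw.es_index, raw.next_ed_index)
    out = np.stack([resize_frame(m, size, order=0) for m in raw_masks[idx]])
    return MaskBlock(data=out.astype(raw_masks.dtype))


def apply_sector_mask(block: VideoBlock, sector: np.ndarray) -> VideoBlock:
    """Zero all pixels outside the sector polygon ((row, col) vertices)."""
    sector = np.asarray(sector, dtype=float)
    if sector.ndim != 2 or sector.shape[0] < 3 or sector.shape[1] != 2:
        raise ValueError("sector polygon needs at least 3 (row, col) vertices")
    r, c = sector[:, 0], sector[:, 1]
    area = 0.5 * abs(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))
    if area == 0.0:
        raise ValueError("sector polygon has empty interior")
    shape = block.data.shape[1:]
    inside = polygon2mask(shape, sector)
    return VideoBlock(data=block.data * inside[None].astype(np.float32),
                      view=block.view)


def read_dicom_cycle(path, ed_index: int, es_index: int,
                     next_ed_index: int | None = None) -> RawCycle:
    """Optional DICOM ingestion stub: multi-frame ultrasound to RawCycle."""
    import pydicom  # deferred; pipeline contract starts at RawCycle

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 4:  # RGB -> luma
        arr = arr.mean(axis=-1)
    return RawCycle(frames=arr, ed_index=ed_index, es_index=es_index,
                    next_ed_index=next_ed_index)
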
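"""ROI determination for lensless calcium-imaging videos.

Without focusing optics the light of each neuron spreads over many
pixels, so classical segmentation of cell bodies is not possible.  The
pipeline here instead finds regions that are persistently brighter than
their local surroundings:

1. every frame of the %dF/F video is binarized with a Gaussian-weighted
   local (adaptive) threshold,
2. morphological opening removes speckle smaller than the footprint,
3. area opening removes remaining small connected components,
4. the cleaned binary frames are averaged,
5. the average image is adaptively binarized again,
6-7. and cleaned with the same opening / area-opening sequence.

The seven tunables (sigma1, FP1, A1, sigma2, FP2, A2, time) plus the
threshold block size are collected in :class:`AlgorithmParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, grey_opening, label as ndi_label
from skimage.measure import label as sk_label, regionprops

from .stack import DffStack, FrameStack

logger = logging.getLogger(__name__)

#: relative epsilon guarding the strict threshold comparison against
#: kernel-normalization round-off (a constant image must binarize to 0)
_THRESHOLD_EPS = 1e-9

# 8-connectivity within a frame, no connectivity across frames
_STRUCTURE_2D = np.ones((3, 3), dtype=int)
_STRUCTURE_FRAMEWISE = np.zeros((3, 3, 3), dtype=int)
_STRUCTURE_FRAMEWISE[1] = 1


@dataclass
class AlgorithmParams:
    """The tunables of the two-pass ROI determination algorithm.

    ``sigma1``/``sigma2`` are the Gaussian-kernel standard deviations of
    the two adaptive binarizations, ``fp1``/``fp2`` the square opening
    footprint side lengths, ``area1``/``area2`` the minimum connected
    component areas, ``time_frames`` how many leading frames enter the
    per-frame binarization stage (``None`` = all), and ``block_size``
    the local-threshold window side (odd; held fixed because it does
    not influence ROI selection).
    """

    sigma1: float = 1.5
    fp1: int = 3
    area1: int = 0
    sigma2: float = 1.5
    fp2: int = 3
    area2: int = 0
    time_frames: int | None = None
    block_size: int = 15

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma values must be > 0")
        if self.fp1 < 1 or self.fp2 < 1:
            raise ValueError("footprint sides must be >= 1")
        if self.area1 < 0 or self.area2 < 0:
            raise ValueError("areas must be >= 0")
        if self.time_frames is not None and self.time_frames < 1:
            raise ValueError("time_frames must be >= 1")
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")

    def as_dict(self) -> dict:
        return {
            "sigma1": self.sigma1,
            "fp1": self.fp1,
            "area1": self.area1,
            "sigma2": self.sigma2,
            "fp2": self.fp2,
            "area2": self.area2,
            "time_frames": self.time_frames,
            "block_size": self.block_size,
        }


@dataclass
class ROIMask:
    """Final binary ROI mask with summary statistics."""

    mask: np.ndarray
    params: AlgorithmParams
    n_rois: int
    mean_roi_area: float


@dataclass(frozen=True)
class ROI:
    """One labeled connected component of the final mask."""

    label: int
    pixels: tuple[tuple[int, int], ...]  # (row, col) members
    area: int
    centroid: tuple[float, float]  # (row, col)


def compute_dff(
    stack: FrameStack | np.ndarray, n_baseline_frames: int | None = None
) -> DffStack:
    """Per-pixel %dF/F relative to the mean over the baseline frames.

    ``out[t, p] = 100 * (F[t, p] - F0[p]) / F0[p]`` with F0 the mean of
    pixel p over the first ``n_baseline_frames`` frames.  Pixels with
    F0 = 0 are mapped to 0 (logged).
    """
    if isinstance(stack, FrameStack):
        data = stack.data
        fps = stack.fps
        if n_baseline_frames is None:
            n_baseline_frames = stack.n_baseline_frames
    else:
        data = np.asarray(stack)
        fps = 10.0
    if n_baseline_frames is None or n_baseline_frames < 1:
        raise ValueError("n_baseline_frames must be >= 1")
    if data.size == 0 or data.shape[0] == 0:
        raise ValueError("empty stack")
    if n_baseline_frames > data.shape[0]:
        raise ValueError(
            f"n_baseline_frames={n_baseline_frames} exceeds stack length "
            f"{data.shape[0]}"
        )
    f0 = data[:n_baseline_frames].mean(axis=0, dtype=np.float64)
    zero = f0 == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.warning("%d pixels have zero baseline; their dF/F is set to 0", n_zero)
    safe_f0 = np.where(zero, 1.0, f0)
    out = (data.astype(np.float32) - safe_f0.astype(np.float32)) / safe_f0.astype(
        np.float32
    ) * 100.0
    out[:, zero] = 0.0
    return DffStack(
        data=out,
        n_baseline_frames=n_baseline_frames,
        fps=fps,
        n_zero_baseline_pixels=n_zero,
    )


def local_gaussian_threshold(
    image: np.ndarray, sigma: float, block_size: int
) -> np.ndarray:
    """Per-pixel Gaussian-weighted neighborhood mean.

    The threshold of a pixel is the mean of its block_size x block_size
    neighborhood weighted by a Gaussian of standard deviation ``sigma``
    (weights normalized over the window); the image border is reflected.
    Works on a single image (H x W) or frame-wise on a stack (T x H x W).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be odd and >= 3")
    radius = (block_size - 1) // 2
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        return gaussian_filter(image, sigma, mode="reflect", radius=radius)
    if image.ndim == 3:
        return gaussian_filter(
            image, (0, sigma, sigma), mode="reflect", radius=(0, radius, radius)
        )
    raise ValueError(f"expected 2-D image or 3-D stack, got ndim={image.ndim}")


def adaptive_binarize(
    image: np.ndarray, sigma: float, block_size: int = 15
) -> np.ndarray:
    """Gaussian adaptive (local) binarization.

    A pixel is set iff its value strictly exceeds its Gaussian-weighted
    neighborhood mean, so flat regions map to 0 and local maxima to 1.
    """
    image = np.asarray(image, dtype=np.float32)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    threshold = local_gaussian_threshold(image, sigma, block_size)
    scale = max(1.0, float(np.abs(image).max())) if image.size else 1.0
    return (image - threshold > _THRESHOLD_EPS * scale).astype(np.uint8)


def morphological_opening(binary: np.ndarray, footprint_side: int) -> np.ndarray:
    """Opening (erosion then dilation) with a square footprint.

    Erosion sets a pixel iff every pixel under the footprint is set;
    dilation iff any is.  The image is padded with zeros, so features
    touching the border can erode.  Accepts a single image or a stack
    (applied frame-wise).
    """
    if footprint_side < 1:
        raise ValueError("footprint_side must be >= 1")
    binary = np.ascontiguousarray(binary, dtype=np.uint8)
    if footprint_side == 1:
        return binary.copy()
    size = (
        (footprint_side, footprint_side)
        if binary.ndim == 2
        else (1, footprint_side, footprint_side)
    )
    return grey_opening(binary, size=size, mode="constant", cval=0)


def area_opening(
    binary: np.ndarray, min_area: int, connectivity: int = 8
) -> np.ndarray:
    """Remove connected components with area strictly below ``min_area``.

    Components are 8-connected by default (diagonal neighbors merge).
    A component whose area equals ``min_area`` is retained.  Accepts a
    single image or a stack (components never span frames).
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(binary, dtype=np.uint8)
    if min_area <= 1:
        return binary.copy()
    if binary.ndim == 2:
        structure = _STRUCTURE_2D if connectivity == 8 else None
    else:
        structure = _STRUCTURE_FRAMEWISE.copy()
        if connectivity == 4:
            structure[1] = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndi_label(binary, structure=structure)
    if n == 0:
        return binary.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels].astype(np.uint8)


def average_binary(binary_frames: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of binary frames (values in [0, 1])."""
    frames = np.asarray(binary_frames, dtype=np.float32)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("expected a non-empty sequence of equal-shape frames")
    return frames.mean(axis=0)


def determine_rois(
    dff: DffStack | np.ndarray, params: AlgorithmParams
) -> ROIMask:
    """Run the full two-pass ROI determination pipeline.

    The first ``params.time_frames`` frames of the given %dF/F stack are
    binarized and cleaned individually (steps 1-3), averaged (step 4),
    and the real-valued average is binarized and cleaned once more
    (steps 5-7).
    """
    frames = dff.data if isinstance(dff, DffStack) else np.asarray(dff)
    if frames.ndim != 3:
        raise ValueError("expected a T x H x W stack")
    t = frames.shape[0] if params.time_frames is None else params.time_frames
    if t > frames.shape[0]:
        raise ValueError(
            f"time_frames={t} exceeds available frames {frames.shape[0]}"
        )
    segment = frames[:t]

    b = adaptive_binarize(segment, params.sigma1, params.block_size)
    b = morphological_opening(b, params.fp1)
    b = area_opening(b, params.area1)
    avg = average_binary(b)
    m = adaptive_binarize(avg, params.sigma2, params.block_size)
    m = morphological_opening(m, params.fp2)
    m = area_opening(m, params.area2)

    labels, n = ndi_label(m, structure=_STRUCTURE_2D)
    foreground = int(m.sum())
    mean_area = foreground / n if n else 0.0
    return ROIMask(mask=m, params=params, n_rois=int(n), mean_roi_area=mean_area)


def label_rois(mask: ROIMask | np.ndarray) -> list[ROI]:
    """8-connected components of the final mask, labeled 1..K."""
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask)
    labeled = sk_label(m > 0, connectivity=2)
    rois = []
    for prop in regionprops(labeled):
        rois.append(
            ROI(
                label=int(prop.label),
                pixels=tuple((int(r), int(c)) for r, c in prop.coords),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    return rois


def roi_trace(
    stack: FrameStack | np.ndarray,
    roi: ROI,
    n_baseline_frames: int | None = None,
) -> np.ndarray:
    """%dF/F trace of one ROI from the raw stack.

    The per-frame value is ``100 * (Fbar_t - F0) / F0`` where Fbar_t is
    the mean raw fluorescence over the ROI pixels at frame t and F0 the
    mean over ROI pixels and baseline frames.
    """
    if not roi.pixels:
        raise ValueError("ROI has no pixels")
    if isinstance(stack, FrameStack):
        data = stack.data
        if n_baseline_frames is None:
            n_baseline_frames = stack.n_baseline_frames
    else:
        data = np.asarray(stack)
    if n_baseline_frames is None or n_baseline_frames < 1:
        raise ValueError("n_baseline_frames must be >= 1")
    rows, cols = zip(*roi.pixels)
    pix = data[:, rows, cols].astype(np.float64)
    fbar = pix.mean(axis=1)
    f0 = fbar[:n_baseline_frames].mean()
    if f0 == 0:
        raise ValueError("ROI baseline fluorescence is zero")
    return ((fbar - f0) / f0 * 100.0).astype(np.float64)


def roi_trace_matrix(
    stack: FrameStack | np.ndarray,
    rois: Sequence[ROI],
    n_baseline_frames: int | None = None,
) -> np.ndarray:
    """Stacked ROI traces, one row per ROI."""
    return np.vstack(
        [roi_trace(stack, roi, n_baseline_frames) for roi in rois]
    )
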
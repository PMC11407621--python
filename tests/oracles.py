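"""Brute-force reference implementations used as independent oracles.

Everything here is written with explicit Python loops and no shared
code with the package, so a test comparing the two catches mistakes in
either the algorithm or its vectorized implementation.
"""

from __future__ import annotations

import numpy as np


def gaussian_threshold_bf(image: np.ndarray, sigma: float, block_size: int) -> np.ndarray:
    """Per-pixel Gaussian-weighted window mean via explicit loops.

    Weights exp(-(dr^2+dc^2)/(2 sigma^2)) over the block_size window,
    normalized to sum 1; borders handled by symmetric reflection.
    """
    radius = (block_size - 1) // 2
    padded = np.pad(image.astype(np.float64), radius, mode="symmetric")
    offsets = np.arange(-radius, radius + 1)
    weights = np.empty((block_size, block_size))
    for a, dr in enumerate(offsets):
        for b, dc in enumerate(offsets):
            weights[a, b] = np.exp(-(dr**2 + dc**2) / (2.0 * sigma**2))
    weights /= weights.sum()
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            window = padded[r: r + block_size, c: c + block_size]
            out[r, c] = float((window * weights).sum())
    return out


def opening_bf(binary: np.ndarray, side: int) -> np.ndarray:
    """Erosion followed by (adjoint) dilation with a square footprint.

    Erosion: a pixel survives iff every pixel under the footprint is
    set, pixels outside the image counting as 0.  Dilation: a pixel is
    set iff the reflected footprint touches a surviving pixel.
    """
    binary = np.asarray(binary).astype(np.uint8)
    if side == 1:
        return binary.copy()
    h, w = binary.shape
    offsets = [(i - side // 2, j - side // 2) for i in range(side) for j in range(side)]
    eroded = np.zeros_like(binary)
    for r in range(h):
        for c in range(w):
            eroded[r, c] = all(
                0 <= r + dr < h and 0 <= c + dc < w and binary[r + dr, c + dc]
                for dr, dc in offsets
            )
    dilated = np.zeros_like(binary)
    for r in range(h):
        for c in range(w):
            dilated[r, c] = any(
                0 <= r - dr < h and 0 <= c - dc < w and eroded[r - dr, c - dc]
                for dr, dc in offsets
            )
    return dilated


def connected_components_bf(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit flood fill."""
    binary = np.asarray(binary)
    h, w = binary.shape
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                comp = set()
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and binary[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                components.append(comp)
    return components


def area_opening_bf(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components with area strictly below min_area."""
    out = np.asarray(binary).astype(np.uint8).copy()
    for comp in connected_components_bf(out):
        if len(comp) < min_area:
            for r, c in comp:
                out[r, c] = 0
    return out


def dff_bf(stack: np.ndarray, n_baseline: int) -> np.ndarray:
    """Element-wise percent change from the per-pixel baseline mean."""
    t, h, w = stack.shape
    out = np.zeros((t, h, w))
    for r in range(h):
        for c in range(w):
            f0 = sum(stack[k, r, c] for k in range(n_baseline)) / n_baseline
            for k in range(t):
                if f0 != 0:
                    out[k, r, c] = (stack[k, r, c] - f0) / f0 * 100.0
    return out


def roi_trace_bf(stack: np.ndarray, pixels, n_baseline: int) -> np.ndarray:
    """Percent change of the ROI-mean fluorescence from its baseline."""
    t = stack.shape[0]
    fbar = np.array(
        [sum(stack[k, r, c] for r, c in pixels) / len(pixels) for k in range(t)]
    )
    f0 = fbar[:n_baseline].sum() / n_baseline
    return (fbar - f0) / f0 * 100.0
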
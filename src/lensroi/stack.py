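"""Core video containers.

A lensless calcium-imaging recording is a dense T x H x W stack of
fluorescence intensities with a designated pre-stimulation baseline
segment at the start.  :class:`FrameStack` holds raw detector counts,
:class:`DffStack` holds the per-pixel percent change relative to the
baseline mean (%dF/F).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """Raw fluorescence video.

    Parameters
    ----------
    data:
        T x H x W array of intensities (floating point).
    fps:
        Acquisition frame rate in frames per second.
    n_baseline_frames:
        Number of leading frames recorded before the stimulus; these
        define the baseline fluorescence F0 of every pixel.
    """

    data: np.ndarray
    fps: float = 10.0
    n_baseline_frames: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a T x H x W stack, got shape {self.data.shape}"
            )
        if not (0 <= self.n_baseline_frames <= self.data.shape[0]):
            raise ValueError(
                f"n_baseline_frames={self.n_baseline_frames} outside "
                f"[0, {self.data.shape[0]}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def baseline(self) -> np.ndarray:
        """View of the pre-stimulation frames."""
        return self.data[: self.n_baseline_frames]

    def post(self) -> np.ndarray:
        """View of the frames after the baseline segment."""
        return self.data[self.n_baseline_frames:]


@dataclass
class DffStack:
    """Per-pixel %dF/F video (percent units).

    ``data[t, i, j] = 100 * (F[t, i, j] - F0[i, j]) / F0[i, j]`` where F0
    is the per-pixel mean over the baseline frames.  Pixels whose
    baseline mean is zero are mapped to 0 everywhere (their count is
    kept in ``n_zero_baseline_pixels``).
    """

    data: np.ndarray
    n_baseline_frames: int
    fps: float = 10.0
    n_zero_baseline_pixels: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def post(self) -> np.ndarray:
        """View of the post-baseline (analysis) segment."""
        return self.data[self.n_baseline_frames:]
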
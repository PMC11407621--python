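"""Reading and writing stacks, ground truth and result tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .roi import ROI
from .simulator import NeuronSpec, SimulatedDataset
from .stack import FrameStack


def read_stack(
    path: str | Path, fps: float = 10.0, n_baseline_frames: int = 0
) -> FrameStack:
    """Load a video stack from a multi-page TIFF or a .npy array file.

    A single 2-D image is promoted to a stack of one frame; dtype is
    promoted to floating point.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            data = tifffile.imread(path)
        elif path.suffix.lower() == ".npy":
            data = np.load(path)
        else:
            raise ValueError(f"unsupported stack format: {path.suffix!r}")
    except (ValueError,):
        raise
    except Exception as exc:  # truncated/corrupt files
        raise ValueError(f"could not read stack from {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"could not read stack from {path}: empty or truncated file")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"expected a 2-D image or T x H x W stack, got shape {data.shape}"
        )
    return FrameStack(
        data.astype(np.float32), fps=fps, n_baseline_frames=n_baseline_frames
    )


def write_stack(path: str | Path, stack: FrameStack | np.ndarray) -> Path:
    """Write a stack as multi-page float32 TIFF or .npy (by extension)."""
    path = Path(path)
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    data = data.astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".npy":
        np.save(path, data)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r}")
    return path


def write_ground_truth(path: str | Path, dataset: SimulatedDataset) -> Path:
    """Ground truth (neurons, patterns, seed, config) as JSON."""
    path = Path(path)
    config = dataclasses.asdict(dataset.config)
    config["pattern_params"] = {
        name: dataclasses.asdict(level)
        for name, level in dataset.config.pattern_params.items()
    }
    payload = {
        "seed": dataset.seed,
        "config": config,
        "neurons": [dataclasses.asdict(n) for n in dataset.neurons],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_ground_truth(path: str | Path) -> list[NeuronSpec]:
    payload = json.loads(Path(path).read_text())
    return [NeuronSpec(**n) for n in payload["neurons"]]


def write_spike_matrix(path: str | Path, spikes: np.ndarray) -> Path:
    """Per-neuron, per-frame spike counts as CSV (neurons as rows)."""
    path = Path(path)
    pd.DataFrame(spikes).to_csv(path, index_label="neuron")
    return path


def write_roi_table(path: str | Path, rois: Sequence[ROI]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "label": [r.label for r in rois],
            "area": [r.area for r in rois],
            "centroid_row": [r.centroid[0] for r in rois],
            "centroid_col": [r.centroid[1] for r in rois],
        }
    ).to_csv(path, index=False)
    return path


def write_traces(
    path: str | Path, traces: np.ndarray, labels: Sequence[int]
) -> Path:
    """Long-format CSV of ROI traces: frame, roi_label, dff_percent."""
    path = Path(path)
    frames = np.arange(traces.shape[1])
    parts = [
        pd.DataFrame(
            {"frame": frames, "roi_label": label, "dff_percent": trace}
        )
        for label, trace in zip(labels, traces)
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> tuple[np.ndarray, list[int]]:
    """Inverse of :func:`write_traces`."""
    table = pd.read_csv(path)
    labels = sorted(table["roi_label"].unique())
    traces = np.vstack(
        [
            table.loc[table["roi_label"] == lab]
            .sort_values("frame")["dff_percent"]
            .to_numpy()
            for lab in labels
        ]
    )
    return traces, [int(lab) for lab in labels]


def write_mask(path_base: str | Path, mask: np.ndarray) -> tuple[Path, Path]:
    """Write a binary mask as .npy plus a PNG preview."""
    from PIL import Image

    base = Path(path_base)
    npy_path = base.with_suffix(".npy")
    png_path = base.with_suffix(".png")
    mask = np.asarray(mask, dtype=np.uint8)
    np.save(npy_path, mask)
    Image.fromarray(mask * 255).save(png_path)
    return npy_path, png_path
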
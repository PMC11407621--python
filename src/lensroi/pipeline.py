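"""End-to-end analysis pipeline.

Ties the modules into the full chain used on a recording: per-pixel
%dF/F baselining, two-pass ROI determination, ROI trace extraction,
spectral subtraction against the non-ROI noise reference, PCA + k-means
activity clustering, and designation of the active cluster.  All
artifacts plus a JSON manifest (parameters, seed, versions) are written
to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import (
    active_cluster,
    attach_mean_traces,
    cluster_traces,
    reduce_traces,
)
from .denoise import StftParams, noise_trace, spectral_subtract_matrix
from .io import read_stack, write_mask, write_roi_table, write_traces
from .roi import AlgorithmParams, compute_dff, determine_rois, label_rois, roi_trace_matrix
from .stack import FrameStack

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    input_path: str | Path | None = None
    baseline_frames: int = 9000
    fps: float = 10.0
    params: AlgorithmParams = field(default_factory=AlgorithmParams)
    stft: StftParams = field(default_factory=StftParams)
    variance_threshold: float = 0.95
    k_min: int = 2
    k_max: int = 10
    seed: int = 0
    out_dir: str | Path = "lensroi_out"


@dataclass
class PipelineResult:
    mask: np.ndarray
    roi_labels: list[int]
    traces: np.ndarray
    traces_denoised: np.ndarray
    cluster_labels: np.ndarray
    chosen_k: int
    active_cluster: int
    manifest: dict


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: PipelineConfig, stack: FrameStack | None = None
) -> PipelineResult:
    """Execute the full pipeline and write artifacts to ``out_dir``.

    ``stack`` may be passed directly (e.g. a freshly simulated dataset);
    otherwise it is read from ``config.input_path``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if stack is None:
        if config.input_path is None:
            raise PipelineError("stage 'read' failed: no input stack given")
        stack = _stage("read")(
            read_stack,
            config.input_path,
            fps=config.fps,
            n_baseline_frames=config.baseline_frames,
        )
    dff = _stage("compute_dff")(compute_dff, stack, config.baseline_frames)
    mask = _stage("determine_rois")(determine_rois, dff.post(), config.params)
    rois = _stage("label_rois")(label_rois, mask)
    if not rois:
        raise PipelineError("stage 'label_rois' failed: no ROIs found")
    traces = _stage("roi_trace")(
        roi_trace_matrix, stack, rois, config.baseline_frames
    )
    noise = _stage("noise_trace")(noise_trace, dff, mask)
    denoised = _stage("spectral_subtract")(
        spectral_subtract_matrix, traces, noise, config.stft
    )
    post = denoised[:, config.baseline_frames:]
    reduction = _stage("reduce_traces")(
        reduce_traces, post, config.variance_threshold
    )
    result = _stage("cluster_traces")(
        cluster_traces, reduction, config.k_min, config.k_max, config.seed
    )
    kept_traces = traces[reduction.kept]
    attach_mean_traces(result, kept_traces)
    active = _stage("active_cluster")(
        active_cluster, result, kept_traces, config.baseline_frames
    )

    roi_labels = [r.label for r in rois]
    write_mask(out_dir / "mask", mask.mask)
    write_roi_table(out_dir / "rois.csv", rois)
    write_traces(out_dir / "traces.csv", traces, roi_labels)
    write_traces(out_dir / "traces_denoised.csv", denoised, roi_labels)
    kept_labels = [roi_labels[i] for i in reduction.kept]
    clusters_payload = {
        "chosen_k": result.k,
        "silhouette_by_k": {str(k): v for k, v in result.silhouette_by_k.items()},
        "active_cluster": active,
        "labels": {
            str(lab): int(c) for lab, c in zip(kept_labels, result.labels)
        },
    }
    (out_dir / "clusters.json").write_text(json.dumps(clusters_payload, indent=2))

    manifest = {
        "lensroi_version": __version__,
        "seed": config.seed,
        "baseline_frames": config.baseline_frames,
        "fps": config.fps,
        "params": config.params.as_dict(),
        "stft": dataclasses.asdict(config.stft),
        "variance_threshold": config.variance_threshold,
        "k_min": config.k_min,
        "k_max": config.k_max,
        "input_path": str(config.input_path) if config.input_path else None,
        "n_rois": mask.n_rois,
        "mean_roi_area": mask.mean_roi_area,
        "chosen_k": result.k,
        "active_cluster": active,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        mask=mask.mask,
        roi_labels=roi_labels,
        traces=traces,
        traces_denoised=denoised,
        cluster_labels=result.labels,
        chosen_k=result.k,
        active_cluster=active,
        manifest=manifest,
    )
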
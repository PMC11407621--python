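"""Extract ROI traces, denoise them by spectral subtraction, and cluster.

Pixels outside the ROI mask see the shared stray-light background but not
the neural signal, so their mean trace is a noise reference: its STFT
magnitude spectrogram is subtracted from each ROI trace.  The denoised
traces are PCA-reduced and k-means-clustered; the mean silhouette score
selects the number of clusters.
"""

import numpy as np

from lensroi import (
    AlgorithmParams,
    SimulationConfig,
    active_cluster,
    cluster_traces,
    compute_dff,
    determine_rois,
    label_rois,
    noise_trace,
    reduce_traces,
    roi_trace_matrix,
    simulate_dataset,
)
from lensroi.denoise import spectral_subtract_matrix
from lensroi.evaluation import roi_pattern_labels

config = SimulationConfig(n_pre_frames=3000, n_post_frames=9000, seed=1)
dataset = simulate_dataset(config)
dff = compute_dff(dataset.frames)
mask = determine_rois(dff.post(), AlgorithmParams())
rois = label_rois(mask)

traces = roi_trace_matrix(dataset.frames, rois)
reference = noise_trace(dff, mask)
denoised = spectral_subtract_matrix(traces, reference)
print(f"{len(rois)} ROI traces; noise reference sd {reference.std():.2f}%% dF/F")

post = denoised[:, config.n_pre_frames:]
reduction = reduce_traces(post, variance_threshold=0.95)
print(f"PCA kept {reduction.n_components} components "
      f"({reduction.explained_variance_ratio.sum():.1%} of variance)")

result = cluster_traces(reduction, k_min=2, k_max=10, seed=0)
print(f"silhouette-selected k = {result.k}")
for k, s in sorted(result.silhouette_by_k.items()):
    print(f"  k={k}: mean silhouette {s:.3f}")

active = active_cluster(result, traces[reduction.kept], config.n_pre_frames)
print(f"active cluster (highest post-stimulation mean): {active}")

# compare the partition against the ground-truth activity patterns
patterns = roi_pattern_labels(rois, dataset.neurons)
for lab in range(1, result.k + 1):
    members = [
        patterns.get(rois[i].label, "no neuron")
        for i, c in zip(reduction.kept, result.labels)
        if c == lab
    ]
    print(f"cluster {lab}: {dict((p, members.count(p)) for p in set(members))}")
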
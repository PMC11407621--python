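"""Scoring ROI masks against simulator ground truth.

A ground-truth neuron counts as detected when its integer pixel
position lies inside any ROI of the final mask.  Detection fractions
are reported per activity pattern and for the pooled "active" group
(pattern 1 and pattern 2).  Replicate studies repeat the whole
simulate-detect-score loop over many seeds; the depth analysis pools
missed neurons to show how detectability falls with distance from the
sensor; and the PLS sensitivity model regresses mean ROI area on the
seven algorithm parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .roi import AlgorithmParams, ROIMask, compute_dff, determine_rois
from .simulator import (
    PATTERN1,
    PATTERN2,
    UNRESPONSIVE,
    NeuronSpec,
    SimulationConfig,
    simulate_dataset,
)
from .stack import DffStack

logger = logging.getLogger(__name__)

PARAM_COLUMNS = ["sigma1", "fp1", "area1", "sigma2", "fp2", "area2", "time_frames"]


@dataclass
class PatternAccuracy:
    detected: int
    total: int

    @property
    def fraction(self) -> float:
        return self.detected / self.total


@dataclass
class AccuracyReport:
    """Detection outcome of one replicate."""

    per_pattern: dict[str, PatternAccuracy]
    detected_neurons: list[NeuronSpec]
    undetected_neurons: list[NeuronSpec]
    seed: int | None = None

    @property
    def active_fraction(self) -> float | None:
        """Fraction of pattern-1/pattern-2 neurons enclosed by an ROI."""
        acc = self.per_pattern.get("active")
        return acc.fraction if acc else None


def detection_accuracy(
    mask: ROIMask | np.ndarray,
    neurons: Sequence[NeuronSpec],
    seed: int | None = None,
) -> AccuracyReport:
    """Score a mask: a neuron is detected iff its pixel is foreground.

    Fractions are computed per pattern and for the pooled active group;
    patterns with no neurons are absent from the report (not zero).
    """
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask)
    detected_flags = [bool(m[n.y_px, n.x_px]) for n in neurons]
    per_pattern: dict[str, PatternAccuracy] = {}
    for pattern in (PATTERN1, PATTERN2, UNRESPONSIVE):
        members = [f for n, f in zip(neurons, detected_flags) if n.pattern == pattern]
        if members:
            per_pattern[pattern] = PatternAccuracy(sum(members), len(members))
    active = [
        f for n, f in zip(neurons, detected_flags) if n.pattern in (PATTERN1, PATTERN2)
    ]
    if active:
        per_pattern["active"] = PatternAccuracy(sum(active), len(active))
    return AccuracyReport(
        per_pattern=per_pattern,
        detected_neurons=[n for n, f in zip(neurons, detected_flags) if f],
        undetected_neurons=[n for n, f in zip(neurons, detected_flags) if not f],
        seed=seed,
    )


@dataclass
class ReplicateSummary:
    """Aggregate of a replicate detection study."""

    reports: list[AccuracyReport]
    n_replicates: int
    n_full_capture: int  # replicates detecting 100% of active neurons
    n_ge90_capture: int  # replicates detecting >= 90% of active neurons
    histogram_counts: np.ndarray  # active-fraction counts in 10% bins
    histogram_edges: np.ndarray

    @property
    def fraction_full_capture(self) -> float:
        return self.n_full_capture / self.n_replicates

    @property
    def fraction_ge90_capture(self) -> float:
        return self.n_ge90_capture / self.n_replicates


def _histogram(fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 10%-wide bins over [0, 1], the last bin right-inclusive at 100%
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(fractions, bins=edges)
    return counts, edges


def replicate_study(
    config: SimulationConfig,
    params: AlgorithmParams,
    n_replicates: int,
    seeds: Sequence[int] | None = None,
) -> ReplicateSummary:
    """Simulate, detect and score ``n_replicates`` independent datasets.

    Each replicate re-runs the full chain simulate_dataset ->
    compute_dff -> determine_rois (on the post-stimulation %dF/F
    segment) -> detection_accuracy.  Seeds default to a deterministic
    stream derived from ``config.seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seeds is None:
        seed_rng = np.random.default_rng(config.seed)
        seeds = seed_rng.integers(0, 2**31 - 1, size=n_replicates).tolist()
    elif len(seeds) != n_replicates:
        raise ValueError("len(seeds) must equal n_replicates")

    reports = []
    for seed in seeds:
        dataset = simulate_dataset(dc_replace(config, seed=int(seed)))
        dff = compute_dff(dataset.frames)
        mask = determine_rois(dff.post(), params)
        reports.append(detection_accuracy(mask, dataset.neurons, seed=int(seed)))
        del dataset, dff, mask

    fractions = np.array(
        [r.active_fraction for r in reports if r.active_fraction is not None]
    )
    counts, edges = _histogram(fractions)
    return ReplicateSummary(
        reports=reports,
        n_replicates=n_replicates,
        n_full_capture=int(np.sum(fractions >= 1.0)),
        n_ge90_capture=int(np.sum(fractions >= 0.9)),
        histogram_counts=counts,
        histogram_edges=edges,
    )


@dataclass
class DepthAnalysis:
    """Depth distribution of missed active neurons."""

    undetected_counts_by_depth: dict[int, int]
    mean_depth_undetected: float | None
    mean_depth_detected: float | None


def undetected_depth_analysis(reports: Iterable[AccuracyReport]) -> DepthAnalysis:
    """Pool active neurons across replicates and compare depths.

    Deeper neurons spread their light over more pixels with a dimmer
    peak, so missed neurons should sit farther from the sensor on
    average than detected ones.
    """
    undetected = []
    detected = []
    for report in reports:
        undetected += [
            n for n in report.undetected_neurons if n.pattern in (PATTERN1, PATTERN2)
        ]
        detected += [
            n for n in report.detected_neurons if n.pattern in (PATTERN1, PATTERN2)
        ]
    depths = sorted({n.z_px for n in undetected})
    counts = {z: sum(1 for n in undetected if n.z_px == z) for z in depths}
    return DepthAnalysis(
        undetected_counts_by_depth=counts,
        mean_depth_undetected=(
            float(np.mean([n.z_px for n in undetected])) if undetected else None
        ),
        mean_depth_detected=(
            float(np.mean([n.z_px for n in detected])) if detected else None
        ),
    )


def parameter_sweep(
    dff: DffStack | np.ndarray, grid: Sequence[AlgorithmParams]
) -> pd.DataFrame:
    """Run the ROI pipeline at every grid point.

    Returns one row per parameter set with the mean ROI area (total
    foreground over component count; 0 for an empty mask) and the
    component count.
    """
    if len(grid) == 0:
        raise ValueError("parameter grid is empty")
    rows = []
    for params in grid:
        mask = determine_rois(dff, params)
        row = params.as_dict()
        if row["time_frames"] is None:
            data = dff.data if isinstance(dff, DffStack) else np.asarray(dff)
            row["time_frames"] = data.shape[0]
        row["mean_roi_area"] = mask.mean_roi_area
        row["n_rois"] = mask.n_rois
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PlsModel:
    """Partial least squares sensitivity of mean ROI area to parameters."""

    coefficients: dict[str, float]  # response units per raw parameter unit
    intercept: float
    r2: float
    rpd: float  # SD(response) / RMSE of leave-one-out prediction
    n_components: int


def pls_parameter_model(
    sweep_table: pd.DataFrame,
    n_components: int = 2,
    response: str = "mean_roi_area",
) -> PlsModel:
    """Fit PLS regression of mean ROI area on the 7 raw-unit parameters.

    Reports per-parameter coefficients on the response scale, the
    in-sample coefficient of determination, and the relative prediction
    deviation (RPD) computed from leave-one-out prediction.
    """
    missing = [c for c in PARAM_COLUMNS + [response] if c not in sweep_table]
    if missing:
        raise ValueError(f"sweep table missing columns: {missing}")
    if len(sweep_table) < n_components + 2:
        raise ValueError("not enough sweep rows for the requested components")
    x = sweep_table[PARAM_COLUMNS].to_numpy(dtype=float)
    y = sweep_table[response].to_numpy(dtype=float)
    constant = [c for c, s in zip(PARAM_COLUMNS, x.std(axis=0)) if s == 0]
    if constant:
        raise ValueError(f"constant parameter columns in sweep: {constant}")

    model = PLSRegression(n_components=n_components)
    model.fit(x, y)
    if y.std() == 0:
        r2 = 0.0  # R^2 undefined for a constant response
    else:
        r2 = float(model.score(x, y))
    coefficients = dict(zip(PARAM_COLUMNS, model.coef_.ravel()))
    intercept = float(model.intercept_.ravel()[0])

    # leave-one-out residuals for the RPD
    loo_pred = np.empty_like(y)
    idx = np.arange(len(y))
    for i in idx:
        rest = idx != i
        m = PLSRegression(n_components=n_components)
        m.fit(x[rest], y[rest])
        loo_pred[i] = m.predict(x[i: i + 1]).ravel()[0]
    rmse = float(np.sqrt(np.mean((y - loo_pred) ** 2)))
    sd = float(y.std(ddof=1))
    rpd = sd / rmse if rmse > 0 else float("inf")
    return PlsModel(
        coefficients=coefficients,
        intercept=intercept,
        r2=r2,
        rpd=rpd,
        n_components=n_components,
    )


def default_sweep_grid(
    seed: int = 0,
    n_points: int = 160,
    sigma_levels: Sequence[float] = (0.5, 1.5, 2.5),
    footprint_levels: Sequence[int] = (2, 3),
    area_levels: Sequence[int] = (0, 9),
    time_levels: Sequence[int] = (50, 500, 1500, 3000),
    tie_prob: float = 0.7,
) -> list[AlgorithmParams]:
    """Randomized two-stage parameter grid for sensitivity sweeps.

    The second-stage sigma and footprint are co-varied with the first
    stage (equal with probability ``tie_prob``, otherwise one level up
    or down), reflecting how the two passes are explored together in
    practice; the resulting predictor multicollinearity is the reason
    partial least squares is the regression of choice here.  Area
    thresholds and the averaging time vary independently.
    """
    rng = np.random.default_rng(seed)
    sigmas = list(sigma_levels)
    footprints = list(footprint_levels)
    p_step = (1.0 - tie_prob) / 2.0

    def neighbor(levels: list, index: int) -> object:
        step = int(rng.choice([-1, 0, 1], p=[p_step, tie_prob, p_step]))
        return levels[min(max(index + step, 0), len(levels) - 1)]

    pool: list[AlgorithmParams] = []
    for _ in range(2):  # two jittered passes over the tied factorial
        for i_s, s1 in enumerate(sigmas):
            for i_f, f1 in enumerate(footprints):
                for a1 in area_levels:
                    for a2 in area_levels:
                        for tf in time_levels:
                            pool.append(
                                AlgorithmParams(
                                    sigma1=s1, fp1=f1, area1=a1,
                                    sigma2=neighbor(sigmas, i_s),
                                    fp2=neighbor(footprints, i_f),
                                    area2=a2, time_frames=tf,
                                )
                            )
    chosen = rng.choice(len(pool), min(n_points, len(pool)), replace=False)
    return [pool[i] for i in chosen]


def roi_pattern_labels(
    rois: Sequence, neurons: Sequence[NeuronSpec]
) -> dict[int, str]:
    """Ground-truth pattern of each ROI that encloses at least one neuron.

    An ROI enclosing several neurons takes the most common pattern among
    them (ties break by pattern order: pattern1, pattern2, unresponsive).
    """
    labels: dict[int, str] = {}
    for roi in rois:
        pixel_set = set(roi.pixels)
        enclosed = [n.pattern for n in neurons if (n.y_px, n.x_px) in pixel_set]
        if enclosed:
            order = (PATTERN1, PATTERN2, UNRESPONSIVE)
            labels[roi.label] = max(order, key=lambda p: (enclosed.count(p), -order.index(p)))
    return labels
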
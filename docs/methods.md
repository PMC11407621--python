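# Methods

## The problem

A lensless, implantable CMOS image sensor records calcium-indicator
fluorescence directly against brain tissue, with no focusing optics.
Each active neuron illuminates a broad patch of the 120 x 40 px sensor;
patches from different neurons overlap, edges are ambiguous, and every
pixel carries non-stationary stray-light noise.  Cell-segmentation
tools built for focused microscopy (CNMF, Suite2p and relatives) assume
compact cell footprints and do not transfer to this geometry.  The
package instead determines regions of interest (ROIs) as locations that
are persistently brighter than their local surroundings, then separates
the resulting (deliberately over-complete) ROI set by activity.

## ROI determination

All frames are first baselined per pixel,
dF/F(t, p) = 100 * (F(t, p) − F0(p)) / F0(p), with F0 the mean of the
pre-stimulation segment.  Pixels with F0 = 0 map to 0 and are logged.

The mask is built in two passes over the analysis segment:

1. each frame is binarized with a Gaussian adaptive threshold: a pixel
   is set iff its value strictly exceeds the Gaussian-weighted mean
   (kernel sd sigma1, window `block_size`, reflected borders) of its
   neighborhood;
2. morphological opening (square footprint, side FP1) removes speckle;
3. area opening removes 8-connected components smaller than A1 pixels;
4. the cleaned binary frames are averaged;
5. the real-valued average is adaptively binarized again (sigma2);
6. opened (FP2); 7. area-opened (A2).

Step 5 thresholds the raw average without rescaling — the adaptive
threshold is scale-free, so rescaling would change nothing.

Numerical choices:

* The threshold comparison is strict with a relative epsilon of 1e-9
  times the image scale, so that a perfectly constant image binarizes
  to all-zero despite kernel-normalization round-off.
* Opening is erosion followed by adjoint dilation with zero padding
  (border features can erode).  Even footprint sides are accepted —
  they follow the `scipy.ndimage.grey_opening` window convention, and
  the operation remains idempotent and anti-extensive.
* Components use 8-connectivity (diagonal fragments of one source stay
  merged); `min_area` is a strict lower bound, so a component exactly
  at the threshold is kept.
* `block_size` defaults to 15 and is kept out of the tuned parameter
  set; the window size does not influence which ROIs are selected.
* `time_frames` defaults to the whole analysis segment.

A known degeneracy: with no final opening (FP2 = 1) and a noisy average
image, the strict local threshold sets roughly half the background
pixels and 8-connected exceedances percolate into one giant component.
This is a property of scale-free local thresholding, not of the
implementation; sweep grids therefore use FP >= 2.

## Trace extraction and denoising

Each ROI trace is dF/F of the ROI-mean fluorescence (F-bar_t vs the
ROI baseline mean).  The mean dF/F of all non-ROI pixels serves as a
noise reference: both are short-time Fourier transformed (Hann window,
256-frame segments ~ 25.6 s at 10 fps, 50% overlap — a perfect
reconstruction configuration resolving structure below 0.05 Hz), the
noise magnitude spectrogram is subtracted with half-wave rectification,
and the trace is re-synthesized with its own phase.  The window
parameters are configurable; the defaults are a package choice, not a
measured constraint.

## Activity clustering

Post-stimulation denoised traces are first averaged into 60 equal
temporal bins (one per minute of the default one-hour window): the
activity patterns differ on the timescale of minutes, and without
binning the Euclidean distances between 36,000-sample traces are
dominated by frame-level noise, leaving the selected cluster count on
a knife edge between "active vs. inactive" (k = 2) and the full
three-pattern partition.  Binned traces are then centered and divided
by (sd + floor), where floor is the median per-trace sd.  This "soft"
normalization is deliberate: plain z-scoring maps near-silent traces to
random unit vectors that fragment into many spurious clusters, whereas
soft normalization compares active traces by shape while silent ones
shrink toward the origin and stay together.  PCA retains the smallest
component set explaining 95% of variance; k-means (10 restarts) runs
for k = 2..10 and the k with the highest mean silhouette is chosen
(ties to the smallest k; the global maximum is always used).  The
cluster with the highest time-averaged post-stimulation trace is
designated active.  Zero-variance traces are dropped with a warning
before PCA; a fully degenerate (all-identical) score matrix is an
error.

## The synthetic-data generator

The generator reproduces a stimulation experiment on the lensless
geometry.  Defaults (all configurable):

* field of view 120 x 40 px at 10 fps; 9,000 pre- + 36,000
  post-stimulation frames;
* 30 neurons, centers uniform on x in [5, 35], y in [5, 115] (the 5-px
  device border is avoided as it is noisy in the real device), depth
  z uniform on [4, 8] px = 30-60 um at 7.5 um/px (closer neurons are
  destroyed during implantation);
* pre-stimulation: every neuron fires a single spike with probability
  0.10 per frame; post-stimulation patterns (uniformly assigned):
  pattern 1 = high / medium / low activity over 10 / 20 / 30 min,
  pattern 2 = medium / high / medium / low over 10 / 10 / 20 / 20 min,
  unresponsive = spontaneous statistics continue;
* high = 10 Hz events, 25% bursts; medium = 10 Hz, 1/15 bursts;
  low = 5 Hz, 1/20 bursts; a burst carries uniform 2-5 spikes.
  Events per frame are Poisson(rate/fps), preserving the rates as
  per-second expectations at the ~1 event/frame regime.
  Block boundaries are defined as fractions of the post window
  (10 min = 1/6 of 60), so scaled-down recordings keep every phase.
* calcium transient: instantaneous rise, exponential decay tau = 1 s
  (GCaMP6-like), kernel truncated at 5 tau;
* optics: a source at lateral distance d and depth z contributes
  irradiance proportional to z / (d^2 + z^2)^(3/2) (isotropic point
  source over a planar detector, obliquity included), truncated at
  radius 4z — footprints widen and peaks dim with depth, which is what
  makes deep neurons hard to detect;
* amplitude: 60 detector counts per spike at the source, i.e. a
  single-spike peak of ~3.75% dF/F at z = 4 and ~0.9% at z = 8 over a
  baseline of 100 counts.  This places active neurons clearly above
  the noise floor and the deepest ones near it, the regime in which
  detection errors concentrate at depth;
* noise and background: baseline offset 100 counts; static linear
  illumination gradient (amplitude 10) along the long axis emulating
  uneven LED excitation; a frame-wide AR(1) stray-light term (sd 2,
  tau 10 s) shared by all pixels; slowly drifting spatially correlated
  speckle (sd 1, spatial scale 2 px, tau 30 s) emulating stray light
  scattered through tissue and filter imperfections; white Gaussian
  read noise (sd 1).  Intensities are clipped at zero.

The shared background term is spatially uniform, so it cancels exactly
out of the local-threshold binarization but contaminates every
extracted trace — it is the component the spectral subtraction removes.
The drifting speckle does not average away over frames and is what
produces spurious ROIs containing no neuron, as seen on real devices.

What the generator does **not** emulate: angular sensitivity and
absorption-filter leakage of the real sensor, motion artifacts,
hemodynamic signals, photobleaching, and non-Poissonian firing
statistics.  Passing tests on synthetic data therefore demonstrate the
algorithm's behavior under the stated statistical design, not
performance on any particular in-vivo recording.

## Evaluation

A neuron is *detected* when its integer pixel position lies inside any
ROI (no tolerance radius).  Detection fractions are reported per
activity pattern and for the pooled active group; a pattern with no
neurons is reported as absent rather than zero.  Replicate studies
rerun the full simulate-detect-score chain per seed and report the
fractions of replicates at 100% and >= 90% active capture plus a
10%-binned histogram.  The depth analysis pools missed active neurons
across replicates; because the point-source peak falls as 1/z^2,
missed neurons sit measurably deeper than detected ones.

Parameter sensitivity is modeled by partial least squares regression of
mean ROI area (foreground pixels / component count) on the seven
raw-unit parameters, with 2 latent components (configurable), in-sample
R^2, and a relative prediction deviation SD(y)/RMSE computed from
leave-one-out prediction.  The default sweep grid co-varies the
second-stage sigma and footprint with the first stage (equal with
probability 0.7, otherwise one level off): the two passes are explored
together in practice, and the resulting predictor multicollinearity is
exactly why PLS is the appropriate regression.  Grid levels are
sigma in {0.5, 1.5, 2.5}, FP in {2, 3}, A in {0, 9}, and averaging
times from 5 s to the full segment.  On this design the fitted signs
are stable across simulation seeds: both sigmas positive, both
footprints negative, A2 positive, A1 and time near zero.

## Problem sizes used by the tests and the acceptance script

The replicate study runs 100 replicates with recordings scaled to
3,000 pre- + 9,000 post-stimulation frames (proportions of the
1000-replicate full-length study are preserved by the fractional
activity schedule; the baseline only estimates per-pixel means, for
which 5 minutes is ample).  The cluster-count check runs one full-size
45,000-frame simulation and repeats only the k-means stage over 10
seeds.  The sensitivity sweep uses a 160-point randomized grid on a
reduced 4,000-frame dataset.

## Known limitations

* The rendering model is geometric; no attempt is made to match the
  absolute photon budget of a specific sensor.
* The silhouette criterion takes the global maximum; data with nested
  cluster structure may peak at a secondary local maximum that would
  be scientifically preferable.
* Mean ROI area is a coarse mask summary: deleting small components
  (larger footprints, area thresholds) can raise it even as total
  foreground shrinks, so sensitivity signs depend on the sweep design;
  the co-varied grid above reproduces the expected structure robustly.
* With FP2 = 1 the final mask can percolate (see above); parameter
  choices that skip the final cleaning are outside the intended
  operating range.
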
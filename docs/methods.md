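# Methods

This note documents the model implemented by `covmap`, its assumptions,
the parameters that matter, and the design choices made where the
procedure was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Analysis model

### Network dynamics from BOLD

Per-subject spatial ICA supplies independent components (map + timecourse
pairs); ICA itself is an external interface — any spatial-ICA
implementation may provide the maps, and the conventional decomposition
order (30 components per subject) is a configuration default, not
re-implemented math. Each subject's ICs are assigned to RSN templates by
greedy best-first matching on the absolute Pearson correlation over voxels
(ICA sign is arbitrary, so the better of ±IC is taken; ties break toward
the lower IC index; matches below `min_similarity`, default 0.25, are left
unassigned). Sign-negative matches flip the IC map before use.

For each network, a group component (GC) is the voxelwise one-sample
*t*-map across the contributing subjects' aligned IC maps. Per-subject
network activity is the dot product of the **unthresholded** GC map with
each momentary z-scored BOLD image. Whether the original procedure
weighted by the raw or a thresholded t-map is not determinable from its
description; unthresholded weighting is the default here because
thresholding discards anticorrelated voxels that carry signal, and a
`backproject_thresholded` switch provides the alternative (voxel-p plus
minimum-cluster-size display threshold, default p < 0.005 and 10 voxels,
6-connectivity — a plain cluster-size rule, used for display only).
Stacked activities are normalized to unit sample variance across networks
at every volume, making the dynamics *relative*: a network's value
expresses its momentary prominence against the other networks.

### EEG spectra

Epochs of 256 samples at 100 Hz are cut starting 6560 ms before each scan
marker, placing the EEG window one hemodynamic lag ahead of the volume it
is paired with. The printed window (6560–4010 ms) spans 255 sample
intervals while the epoch length is 256 samples; these are mutually
inconsistent by one sample, and this implementation honours the sample
count — the epoch runs −6560 ms to −4000 ms. Epochs running off the
recording or overlapping an artifact span are masked, not deleted, so the
epoch axis stays aligned with the volume axis; masked pairs are dropped
inside the covariance dot product.

The "10% Hanning" taper is implemented as a Tukey window: cosine ramps
over the first and last 10% of the epoch, flat in between — the
established meaning of that phrase in the EEG software family this
analysis descends from (`taper_fraction` is configurable). Amplitudes are
raw DFT moduli; no 1/N or taper-gain correction is applied because the
normalization below cancels any global scale.

Bin selection: at 100 Hz / 256 samples the spacing is 0.390625 Hz, and
the harmonics k = 3…77 (centres 1.17–30.08 Hz) are retained, giving 75
bins across the nominal 1–30 Hz band. The literal closed interval [1, 30]
would give 74 bins; the k = 3…77 convention is the one consistent with a
75-bin analysis and is the default (`bin_convention="count75"`, with
`"closed_interval"` available).

Normalization is two-stage: (1) per channel and bin, remove the mean over
valid epochs — the covariance then measures *fluctuation* coupling, not
baseline spectra; (2) per epoch and bin, scale the channel vector to unit
sample variance across channels — discarding global power so that only
the spatial pattern remains. Degenerate (constant) vectors map to zero;
all sample SDs in the package use the n−1 denominator, for consistency
with the t statistics.

### Covariance mapping

The covariance is the raw dot product over valid epoch/volume pairs, not
scaled by the pair count — subjects with different numbers of valid pairs
therefore contribute on slightly different scales, and the valid-pair
count is stored alongside for optional rescaling. The full design yields
a 20 × 10 × 75 × 92 tensor. One-sample t-maps across subjects use the
degenerate-variance rule: zero variance with zero mean gives t = 0; zero
variance with nonzero mean stores a flagged ±10¹² sentinel, keeping
arrays finite and serializable. Exact constancy is detected by value
range, not by the computed SD, which can be rounding-level nonzero for
identical large values.

### Band discovery

Each retained bin is described by the concatenation of all networks'
t-values at all electrodes (10 × 92 = 920 features at full scale).
K-means with Euclidean distance, k-means++ initialization and 100
restarts (best within-cluster sum of squares kept) labels the bins;
labels are renumbered by ascending mean member frequency. Contiguity is
not enforced during clustering: the raw label sequence is always
reported, a fragmentation score (fraction of bins outside their cluster's
longest run) quantifies non-contiguity, and one window-3 median-smoothing
pass repairs isolated flips before borders are placed at label
transitions. k is a user choice (default 8, the conventional
delta…beta3 division); `sweep_k` tabulates inertia and fragmentation over
a range but performs no automatic selection.

### Randomization statistics

All tests operate on whole maps, so no per-electrode multiple-testing
correction is involved. p-values use p = (1 + #{null ≥ observed}) /
(1 + n_perm), counting ties as exceedances; the alternative "fraction of
null values larger" can return p = 0, which misstates the evidence a
finite permutation sample can carry. Default n_perm = 5000.

* **Consistency test**: observed statistic is the RMS across channels of
  the across-subject mean map; nulls shuffle each subject's values among
  electrodes independently, preserving per-subject variance while
  destroying shared spatial structure.
* **One-way TANOVA** (repeated measures): statistic is the mean over
  levels of the RMS of (level mean − grand mean); nulls permute each
  subject's maps across levels.
* **Two-factor TANOVA**: main effects collapse the other factor and run
  the one-way scheme. For the interaction, each subject's additive model
  (row effect + column effect + grand mean, per channel) is removed and
  the residual cell means are tested. The null permutes, within each
  subject, the rows (A levels) and columns (B levels) of the residual
  array. This is the package's single largest interpretive decision: the
  obvious alternative — shuffling residual maps freely across all cells —
  breaks the zero-sum constraints that double-centering imposes on the
  residuals, which measurably narrows the null distribution relative to
  the observed statistic (empirical type-I error 0.09–0.16 at α = 0.05
  in 2×2 to 4×4 designs). Row/column permutations preserve those
  constraints exactly, and the calibration suite verifies type-I error in
  [0.03, 0.07] under both global-null and purely additive data. TANOVA
  dissimilarities use plain RMS of difference maps without
  average-reference re-centering or GFP normalization, since covariance
  maps are not potentials.

The full battery on a band-averaged tensor runs one consistency test per
(network, band) map (80 at full scale), the overall RSN × band two-factor
TANOVA, and one one-way TANOVA over networks per band, all with
independent seeds fanned out from a single master seed.

## Synthetic data

The generator emulates the study conditions — 20 subjects, 252 volumes at
TR 1.98 s, 10 networks, 92 channels, 75 bins — directly at the spectral
level, one epoch per volume. Network dynamics are unit-variance AR(1)
series (x_t = φx_{t−1} + √(1−φ²)ε_t); φ defaults to 0.5, a realistic
lag-1 autocorrelation for network timecourses sampled at a ~2-s TR.
Spectral amplitudes are

    a(t, c, f) = Σ_r strength(r, band(f)) · topography_{r, band(f)}(c) · x_r(t) + ε,

with i.i.d. Gaussian noise (sd 1.0) — the simplest model satisfying the
exchangeability assumptions of the randomization tests. Topographies are
unit-RMS signed Gaussian bumps at random positions on a fixed 92-channel
layout shipped as a TSV fixture (no biophysical forward model; patterns
live directly on channels). Bands default to the canonical 8-band
partition; the default coupling strength 0.5 is chosen so planted effects
are detectable with 20 subjects — reported per-network effect sizes that
would allow matching a measured SNR do not exist. Epoch dropout is
modelled by masking, and pairing is positional.

Template maps for the fMRI side are Gaussian blobs on a small voxel grid
(default 12 × 12 × 8); per-subject "IC" maps are templates plus spatial
noise, in shuffled order, with random sign flips standing in for ICA sign
indeterminacy. By default the spatial-noise SD is calibrated so the
expected template–IC correlation is 0.4, the magnitude regime real group
decompositions show (mean spatial similarities of roughly 0.3–0.55); an
explicit `spatial_noise_sd` overrides this.

What the generator does **not** emulate: raw time-domain EEG and scanner
artifacts (gradient, cardioballistic), 1/f spectral structure and its
non-Gaussian amplitude statistics, spatially correlated EEG noise,
hemodynamic convolution (the lag is handled purely by epoch placement),
head-motion or physiological confounds shared between modalities, and
realistic RSN spatial overlap statistics. Passing tests therefore show
that the pipeline's estimators and tests behave correctly under the
stated model — recovery of planted structure, correct null calibration —
not that real recordings would yield any particular result.

## Numerical choices

* Degenerate variance (constant data) uniformly maps to zero output;
  constancy is tested exactly (value range), not via the computed SD.
* The infinite-t sentinel is ±10¹² with a degeneracy flag.
* K-means ties and restarts are controlled by an explicit seed; labels
  are relabelled deterministically by mean member frequency, with stable
  sort.
* Permutation nulls are generated in fixed-size chunks (250 permutations)
  to bound memory at study scale; chunking does not affect the stream of
  random draws for a given seed.
* A single master seed fans out to per-stage seeds through a
  counter-based SeedSequence derivation recorded in the run manifest, so
  stages are independently reproducible and any derived seed stays below
  2³¹.

## Problem sizes used in validation

The automated checks run the full chain at study scale (20 × 252 × 10 ×
92 × 75) for dimension, recovery and significance-ordering checks, and a
reduced chain (20 subjects, 60 volumes, 2 networks, 2 bands over 4 bins,
92 channels) for the 500-dataset × 500-permutation type-I-error
calibration, chosen so each sweep completes in minutes while leaving the
binomial confidence band around α = 0.05 narrow enough to be informative.

## Known limitations

* The IC→template assignment is greedy, not globally optimal; with
  heavily overlapping templates an optimal-assignment (Hungarian) variant
  would differ occasionally.
* Back-projected dynamics mix networks whose template maps overlap
  spatially; recovery of planted topographies is therefore cleaner
  through the ground-truth-dynamics path than through the IC path, and
  real-data covariance maps inherit the same mixing.
* The interaction permutation scheme is exact under exchangeable
  within-subject noise; heteroscedasticity across cells is not handled.
* No multiple-comparison correction is applied across the 80 consistency
  tests; the significance count is to be read as such.
* The real-data ingestion path (NIfTI BOLD, IC maps, continuous EEG with
  markers) is format-thin: no fMRI preprocessing, EEG artifact
  correction, channel interpolation or inverse solutions are provided —
  inputs are assumed cleaned, filtered to the analysis band and
  downsampled.
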
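# Methods

`spectramap` reimplements, as a tested pipeline, a regression-based analysis
for mapping spectrally tuned neuronal responses in whole-CNS two-photon
calcium imaging of larval zebrafish expressing nuclear-localized GCaMP6s.
This note records the model, the parameter choices that matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Stimulation protocol and timeline

Four LED channels (L1 = UV 365 nm, L2 = violet 420 nm, L3 = blue 470 nm,
L4 = red 600 nm) match the absorption peaks of the four zebrafish cone
types (362 / 415 / 480 / 570 nm). The canonical protocol presents twelve
100 ms flashes, 12.5 s apart, in the order L1 L2 L3 L4 repeated three
times, after a 20 s rest. One plane is imaged for 418 frames at 420 ms per
frame (~176 s). One repetition of the four stimuli occupies a 50 s block.
A fixed shuffled ordering (L3 L4 L2 L1 L4 L3 L1 L2 L2 L3 L4 L1) is used to
test that spectral identities do not depend on stimulus order.

Frame timestamps are taken as frame starts; whether the original
acquisition timestamps frames at their start or midpoint is not knowable
from the recording parameters alone and the choice only shifts every
regressor and trace by at most half a frame, uniformly.

`n_frames = 418` is taken as authoritative over the rounded "176 s"
(418 × 0.42 s = 175.56 s).

## Calcium impulse response function (CIRF)

A brief activity event produces the stereotyped fluorescence transient

    k(t) = exp(-t / tau_decay) - exp(-t / tau_rise),  t > 0,

peak-normalized, with tau_rise = 1.5 s and tau_decay = 2.1 s. The peak
occurs at t* = tau_r tau_d / (tau_d - tau_r) · ln(tau_d / tau_r) ≈ 1.77 s
and the transient decays into the noise well before the next stimulus
12.5 s later. Only the relative shape matters downstream because design
columns are renormalized.

## Design matrix

For each channel, a boxcar (1 during that channel's flashes) on a 10 ms
grid is convolved with the CIRF and sampled at frame times; frames flagged
as stimulus-contaminated receive the same linear interpolation applied to
the traces; each column is scaled to unit L2 norm. The 10 ms grid is
needed to resolve the 100 ms flash — a coarser grid (e.g. a tenth of the
frame period, 42 ms) samples each flash with two or three points depending
on its phase and perturbs relative bump amplitudes by several percent.

The maximum off-diagonal entry of GᵀG is reported as an orthogonality
diagnostic. With the canonical 12.5 s spacing it is ~9 × 10⁻³ — the kernel
tail at 12.5 s is ~2% of peak, so percent-level column overlap is
intrinsic — and the default tolerance is 10⁻², above which a warning (not
an error) is raised. Spacings of 30 s or more drive the diagnostic below
10⁻³, where the projection estimator and a general least-squares solve
agree to high precision.

## Stimulus-frame removal

Fluorescence frames whose scan interval overlaps a flash carry stimulus
bleed-through and are masked, then filled by linear interpolation from
the nearest clean frames. On the canonical timeline the flash onset phase
advances 0.762 frames per event, so two of the twelve flashes straddle a
frame boundary: 14 frames are masked (one or two per flash), not twelve.

## Baseline, dF/F0, smoothing

F0 is a running-window statistic of the raw footprint fluorescence:
the 10% quantile of a 21 s window evaluated every 0.84 s and interpolated
to all frames with a shape-preserving monotone (PCHIP) interpolant. This
reimplements the behaviour of MATLAB `msbackadj` at its defaults; the
quantile is configurable. dF/F0 = (F − F0)/F0, then a centered 2.1 s
(5-frame) moving average with shrinking symmetric windows at the edges
(endpoints preserved), matching MATLAB `smooth`.

A deliberate property of a low-quantile baseline: on pure noise it sits
~1.3 noise-sd below the mean, so null dF/F0 carries a small positive
offset — the invariant the estimator guarantees is that each trace's 10th
percentile is pinned at zero. The offset is shared by experiment and
control recordings and is removed from the regression by the intercept
projection (below), so neither detection nor FDR calibration is affected.

For cohort-scale runs the windowed order statistics are computed in
single precision (relative error ~10⁻⁷, far below physiological noise);
small inputs use double precision.

## Regression and T-scores

With unit-norm, near-orthogonal columns the least-squares coefficients
are β = Gᵀ(dF/F0); the per-channel score is

    T_i = beta_i / sqrt(rss / (n - 3)),   n = 418,

and T_4D = sqrt(T_U² + T_V² + T_B² + T_R²) is the spectrally agnostic
responsiveness statistic. The n − 3 degrees of freedom with four
regressors is nonstandard but is kept literally: it rescales all T by one
common constant and cancels from any threshold chosen on the same scale.

`regress_all` projects the constant component out of both the traces and
an internal copy of the design (demeaned, renormalized columns) before
fitting — the orthogonal-projection form of an intercept. Without it,
(a) the positive DC offset of null dF/F0 couples to the nonnegative
columns and biases every null T upward by roughly +9, destroying the
symmetry of the null distribution, and (b) broadband responders' own
signal DC lands in the residual, inflating rss ~40-fold and crushing
their T-scores. The stored `DesignMatrix` keeps its nonnegative columns.
A zero-residual fit maps T to a finite ±10⁶ sentinel so tables stay
serializable.

## Threshold selection at 1% FDR

A control recording (no stimulation) is passed through the identical
pipeline. Because no channel ordering is preferable under the null, each
control ROI's four T values are pooled over all 24 permutations, making
the null exchangeable across channels by construction. For each channel
(and for T_4D, whose null is the symmetrized control mapped through the
same norm) the empirical tail ratio

    FDR(t) = [#{ctrl ≥ t} / N_ctrl] / [#{exp ≥ t} / N_exp]

is evaluated on the grid of observed experimental values, and the chosen
threshold is the smallest t with FDR(t) ≤ 0.01. Survival-function counts
are used, not density fits. The estimator is conservative by the null
fraction π₀ (≈ 0.98 here). Threshold granularity degrades with cohort
size: tail counts of a few hundred ROIs force the threshold toward the
extreme of the pooled null, so small demonstrations select conservatively
and with visible seed-to-seed variation; calibration is verified at
50,000 ROIs over ten seeds, where the mean realized false-positive
fraction stays at or below the nominal 1%.

## Peak-consistency filter

Each trace is renormalized to its own maximum; local maxima with
topographic prominence ≥ 0.3 are found (`scipy.signal.find_peaks`); a
channel passes only if every one of its post-flash windows (flash onset to
next onset, the last capped at 12.5 s) contains at least one qualifying
peak — three peaks for three repetitions. Note the contract this
implies: a channel whose response is below 30% of the neuron's maximum
response is by construction undetectable, whatever the SNR.

## Negative (light-inhibited) responders

No selection rule for negative responses is stated by the analysis this
reimplements; the rule here is the package's own. The mirrored criterion
(T_i ≤ −threshold_i plus trough consistency on −dF/F0) cannot operate on
the standard dF/F0: an inhibition dip lasting ~8 s fills ~38% of a 21 s
window — beyond the 10th percentile's breakdown point — so the running
baseline tracks the dip and flattens it away. The negative test therefore
recomputes dF/F0 against a median (q = 0.5) running baseline, robust to
dips shorter than half a window, rescoring T on that trace before applying
the mirrored threshold and the trough filter. Neurons are classified with
a single sign: a positively selected neuron is never also reported
negative (strong positive responses induce small negative cross-channel
T through the intercept projection).

## Tbar barcoding and aggregation

Tbar = 8·L1 + 4·L2 + 2·L3 + 1·L4 over the per-channel pass flags; 15
nonzero codes, a bijection with the flag tuples; 8/4/2/1 are the
single-wavelength classes (UV / violet / blue / red). Class-average
traces first average each neuron's three 50 s repetition blocks, then
average across neurons; classes under 10 neurons are kept in tables but
flagged unreported. Identity stability between the standard and shuffled
protocols is the fraction of ROIs selected under either whose codes agree.

Region tallies assign each ROI the atlas label at its centroid voxel
(T telencephalon, E eyes, D diencephalon, M mesencephalon,
R rhombencephalon, S spinal cord), normalize counts to 1 within each larva
across regions, and average across larvae with zero-contribution larvae
included as zero vectors; the standard error uses ddof = 1 over all
larvae.

## Synthetic-data generator

The generator defines the conditions every guarantee is tested under:

- ~2% of neurons respond (`responder_fraction = 0.02`); 30% of responders
  are multi-channel (2–4 channels uniformly); 2% of responders are
  negative, placed preferentially in the diencephalic slab.
- Response amplitude is a neuron-level log-normal (median 0.8 dF/F0,
  sigma 0.4) modulated per channel by a narrow log-normal factor
  (sigma 0.15), floored at 5× the noise sd. Amplitude is modelled as a
  cell property — multi-wavelength neurons respond with comparable
  magnitude on their effective channels — consistent with the
  relative-prominence contract of the peak filter; an independent
  per-channel draw would make a fraction of multi-channel barcodes
  unrecoverable at any SNR. Inhibited amplitudes are capped at 0.9
  (fluorescence cannot fall below zero).
- Trace tier: F = baseline × max(1 + drift + sign·Σ amp·CIRF, 0.01) +
  Gaussian noise of sd 0.05 × baseline; drift is three low-frequency
  sinusoids (5% amplitude, 60 s timescale) with random phases.
- Movie tier: each nucleus is a Gaussian blob (sigma 1.8 px) whose
  integrated brightness follows its trace, on a flat background with
  shot-like noise (Gaussian, sd = sqrt(mean)); optional global
  bleed-through on flash-overlapping frames exercises frame removal.
- Centroids are placed by seeded dart-throwing at least two nucleus
  diameters apart within a plane; random sequential placement saturates
  near ~350 nuclei per 128×256 plane at that spacing, and impossible
  densities are rejected.
- The toy atlas is a deterministic slab partition (eyes as lateral
  lobes), not a real reference brain; registration is out of scope and
  coordinates are assumed pre-registered.

Not emulated: optics (PSF anisotropy, scattering), motion, eye movement,
neuropil contamination, overlapping nuclei beyond a warning, spectral
cross-talk between cone types and LEDs (ground-truth identities are
exact), and any physiological amplitude or noise statistics beyond the
stated parametric forms — the generator's noise floor and amplitude
distribution are stated, not fitted to data. Passing tests therefore
demonstrate the internal correctness and calibration of the pipeline
under these assumptions, not performance on real recordings.

## Nucleus detection

Detection runs on the temporal maximum-intensity projection: difference
of Gaussians (sigmas radius/1.5 and 2×radius, radius 2.5 px), threshold
at the larger of the 95th percentile of the band-passed image and a
robust noise floor (median + 6 robust sd), then non-maximum suppression
at 4 px. The dual threshold adapts to both densely and sparsely populated
fields. Every accepted nucleus receives the fixed 13-pixel diamond
footprint (row widths 1, 3, 5, 3, 1); footprints within a plane are kept
disjoint by greedily dropping the dimmer of any conflicting pair; F(t) is
the footprint sum. The original segmentation routine is unpublished;
these internals are the package's choice and fully configurable.

## Problem sizes used in validation

FDR calibration: ten cohorts of 50,000 neurons with matched no-stimulus
controls (trace tier). Recovery and barcode agreement: 5,000 neurons.
Identity stability: 400 neurons, noiseless. Segmentation quality: three
two-plane movies of 300 neurons at 192×384 px. The movie-tier end-to-end
round trip uses 1,200 neurons over four planes; at that cohort size the
tail-ratio thresholds are intrinsically conservative (see above), which
bounds the achievable per-channel sensitivity in that test.

## Known limitations

- The tail-ratio FDR thresholds distributions, not per-neuron q-values;
  no per-ROI significance is reported.
- Slow responders are invisible by construction: the regressors encode
  the stated CIRF only, and ON/OFF discrimination is impossible with
  100 ms flashes.
- The cone cross-talk estimate uses a Govardovskii A1 alpha-band template
  with rectangular LED bands; only the zero-cross-talk case of the red
  LED and the qualitative ordering of coefficients are asserted, since
  exact coefficients depend on measured spectra not reproduced here.
- 3D (cross-plane) ROI merging and motion correction are out of scope.
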
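# Methods

`sozloc` localizes the seizure-onset zone (SOZ) at the level of
individual SEEG contacts from interictal recordings.  The pipeline has
five stages: biomarker detection, contact-feature aggregation, feature
selection, classification, and volume rendering.  This note documents
the models, the parameters that matter, the numerical conventions, and
what the synthetic data can and cannot show.

## Biomarker detection

### High-frequency oscillations

Ripples (80–250 Hz) and fast ripples (250–500 Hz) are screened per
channel and band:

1. **Band-pass.** Zero-phase FIR (Hamming window, default 257 taps,
   applied forward–backward), giving >40 dB attenuation one octave
   outside the band at 2048 Hz.  The envelope is the magnitude of the
   analytic signal, smoothed with a 10 ms moving average.  Smoothing is
   applied to the envelope, not to the band signal: a 10 ms average
   inside the ripple band would null the carrier itself.
2. **Baseline.** A per-sample spectral flatness statistic is computed
   from the Stockwell transform over 81–500 Hz: at every instant, the
   power across frequency voices is normalized to a distribution and its
   Shannon entropy taken.  Flat (baseline-like) spectra give entropy near
   `log(n_voices)`; oscillatory events concentrate power and depress it.
   Non-overlapping 10 ms windows (`fs/100` samples) in which the entropy
   stays at or above 90% of its recording-wide maximum and the rectified
   filtered signal stays within 10 µV are pooled as baseline.  The
   detection thresholds are empirical-CDF percentiles over that pool:
   `thr` (95th percentile of the envelope) and `thr_filt` (99th
   percentile of the rectified filtered signal).  On pure 1/f noise the
   entropy gate keeps roughly a fifth of all windows — it deliberately
   excludes high-envelope, event-like noise excursions, so `thr` sits
   slightly below the whole-signal 95th percentile.
3. **Screening.** A candidate is a maximal run with envelope
   ≥ `0.99·thr` lasting at least 20 ms (`0.02·fs`), with peak envelope
   below an artifact cap (30 µV for ripples, 20 µV for fast ripples,
   both in envelope microvolts by this package's convention — the
   recording scale makes the unit a convention, so both caps are
   parameters).  A candidate is accepted when the filtered signal makes
   at least 6 positive-going crossings of `+thr_filt` inside the run.
   One positive crossing corresponds to one oscillation cycle, so the
   crossing count equals the oscillation count; counting rectified
   crossings instead would accept 3-cycle events as "six oscillations"
   and, in our pilot runs, floods the detector with sustained noise
   excursions (precision 0.34 instead of ≈1.0 on the synthetic
   benchmark).  Accepted events closer than 10 ms are merged.
4. **Co-occurrence.** An R&FR event is emitted for every ripple whose
   span overlaps a fast ripple on the same contact, with the union span.

The Stockwell transform is computed by the standard frequency-domain
voice method with a 5 Hz frequency stride (84 voices over 81–500 Hz) to
bound memory at long recordings; the entropy criterion is insensitive to
the stride (tested at 5 vs 10 Hz).  The 20 ms condition is read as "the
envelope exceeds threshold throughout the window", the strict reading;
the merge step makes the alternative (any-window) reading nearly
equivalent in practice.

### Spikes

The spike stage is a pluggable registry: any callable returning peak
times and 5 s peak-centered segments can occupy a detector column, and
per-detector event streams are kept separate so the feature table has
one spike-rate column per detector.  The shipped reference detector
flags samples whose amplitude z-score and rectified-slope z-score both
exceed thresholds (default 4 SD each) with a half-height width between
15 and 80 ms and a 150 ms refractory period.  It is deterministic,
DC-invariant, and monotone in its thresholds.  Deep pre-trained
detectors are deliberately out of scope; the registry is the interface
for them.

## Contact features

Rates are events per minute over the analysis window (the recording
duration by default; clinically a 30 min interictal segment).  The
**normalized pathological ripple rate** applies the "regional + 10%
threshold": subtract the region's published 95th-percentile
physiological ripple rate (region 2: 19.5, region 7: 3.5, region 8:
2.7, region 9: 2.0 events/min), clamp negatives to zero, then zero the
contacts whose ripple *count* falls strictly below the empirical 10th
percentile (linear interpolation) of the patient's per-contact counts.
Boundary ties are kept.  A literal "fewer than 10% of the patient's
total ripple count" rule is available behind `count_rule=
"total_fraction"`; the quantile reading is the default because the
published formula is a quantile.  Regions without a published constant
get 0 with a warning (subtracting an unknown constant silently would
corrupt results); a strict mode raises instead.

Energy features are medians over the per-event feature vectors of each
kind on a contact.  Per event, features come from three domains:

* time (energy, duration) — HFO kinds only, since HFO length is
  informative;
* Fourier: max/mean/min of the magnitude spectrum, spectral spread
  ("peak frequency" = max − min of the transform magnitudes, the
  convention used for this feature; an argmax-frequency variant is a
  flag), total power, median PSD, Shannon entropy of the normalized PSD,
  max |spectrum|, magnitude variance;
* wavelet: on the a4 and d4 sub-bands of a 4-level db4 decomposition —
  Shannon and Rényi(2) entropies of normalized squared coefficients,
  permutation entropy (order 3, delay 1), sample entropy (m=2,
  r=0.2·SD, with +1 count regularization so short segments stay
  finite), Kraskov k-NN differential entropy (k=4), energy, SVD entropy
  (embedding 10), and Petrosian/Katz/Higuchi (k_max=10) fractal
  dimensions.  Fast ripples and R&FR events are too short for stable
  Kraskov/Rényi estimates, so those two are dropped for them.

With one spike detector registered the default table has 112 feature
columns (3 spike-rate columns when all three detector slots are filled,
plus 2/1/1 HFO rate columns, the normalized rate, and 20/31/27/27
energy medians).  The registry is configurable; no single sub-band
convention reproduces the reference implementation's printed total of
126, so the default is documented rather than forced.  Rate columns of
event-free contacts are exactly 0; their energy columns are imputed with
the per-patient column median and the imputed (contact, column) pairs
are recorded in `table.attrs["imputed"]`.

## Feature selection (ShapHT+)

A gradient-boosted tree ensemble (100 trees, depth 3, learning rate 0.1,
balanced class weights — the published configuration labels this
"random forest" but a learning rate implies boosting, so boosted trees
are primary) is fitted on the table augmented with *shadow features*:
permuted copies of real features.  Exact tree-SHAP attributions give a
local importance `|φ_i^(n)|` per sample and feature and a global
importance (its mean).  The adaptive threshold ramps over L=10
iterations as `c_l · max(shadow global importance)`, `c_l` linear from
0.1 to 1.0; the final iteration decides.  Each feature's relevance is a
one-sided binomial test of its count of samples with local importance
above the threshold, against a null hit probability taken from the
shadows, with Benjamini–Hochberg correction at α=0.05.

Two choices here are the package's own: **(a)** one shadow copy per
real feature rather than a small fixed number — with only a handful of
shadows the real features face ~10× the selection multiplicity of the
noise benchmark and the test is anti-conservative (measured: ≈8 null
selections per 50-feature table versus ≈0.3 after the change);
**(b)** the null hit probability is the *largest* per-shadow-feature
hit rate (Laplace-smoothed), i.e. a real feature must beat the luckiest
pure-noise feature, not the average one.

## Classifier

A four-layer MLP (features → 128 → 128 → 128 → 2, ReLU, dropout 0.3
after layers 1 and 3) with a soft attention block and focal loss,
trained by NAdam for 20 epochs, batch 4, learning rate 1e-4, inputs
z-scored.  Contact rows have no time axis, so attention operates over
the hidden-unit axis of the third layer's activation: each of the 128
units is a one-dimensional token, `u_t = tanh(w_w e_t + b_w)`,
`h_t = softmax_t(u_t u_w)` with scalar trainable `w_w, b_w, u_w`, and
the activation vector is re-weighted by `H·h ⊙ e` (scaled by the unit
count so uniform attention is the identity map).  `u_w` is initialized
at zero, so training starts from the plain MLP.  The generic sequence
form `v = Σ_t h_t e_t` is exposed as `attention_forward`.

Focal loss is `−α_y (1−p_y)^γ log p_y` with γ=2 and α=0.25 for the
positive (SOZ) class, 0.75 for the negative — the canonical imbalance
weighting.  With γ=0 and uniform α it reduces exactly to cross-entropy
(tested to 1e-9).  The entire network, including backpropagation
through the attention softmax and the NAdam update, is implemented in
NumPy with hand-derived gradients, checked against finite differences
in the test suite; at these problem sizes (hundreds of contacts) this
trains in seconds and is exactly reproducible on one CPU.

**Cross-validation** is leave-one-patient-out: each fold tests on one
patient, the next patient in rotation is the validation set (used only
to pick the best epoch by validation focal loss), and the remaining
patients train.  Feature selection, when enabled in the pipeline, is
re-run inside each fold on the training patients only.  Metrics
(sensitivity, specificity, accuracy, PPV, NPV, in percent, SOZ
positive) are computed per patient at threshold 0.5 and averaged
unweighted across patients; undefined metrics (zero denominators) are
reported missing and skipped, never coerced to 0.

## Voxel rendering

Contact probabilities are rendered on a brain-masked grid: boundary
voxels take the minimum predicted probability; voxels within 2 voxels
of a contact take that contact's probability (nearest contact wins);
all other in-mask voxels are a Gaussian-weighted (σ = 5 mm) convex
combination of the contact probabilities and the boundary value, so the
map cannot overshoot the anchor range.  The neighborhood radius and σ
are free parameters of the rendering, not of the science.  Output is
float32 NIfTI; tests use a synthetic ellipsoid mask — MRI
co-registration is out of scope.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* 1/f^β Gaussian background (default β=2, 15 µV RMS — with these
  values the in-band noise sits ~1 µV so the detector's absolute
  constants, the ±10 µV baseline gate and the 30/20 µV caps, operate in
  their intended regimes);
* biphasic sharp-wave spikes (70 ms, optional 200 ms slow wave at 40%
  amplitude, peak 8 background SDs);
* sinusoidal bursts with 8 cycles by default, Hann-tapered with a
  plateau (Tukey window, taper fraction 0.5).  The plateau is
  deliberate: a pure Hann taper keeps a ~27 ms fast-ripple burst above
  the detection threshold for under 20 ms at moderate SNR, so the
  screening criterion could never accept it; a tapered plateau burst
  satisfies both the 20 ms and the 6-oscillation criteria while staying
  band-limited;
* burst SNR defined as peak amplitude over the 95th percentile of the
  contact's pre-injection in-band envelope (default 10 dB), measured
  per contact and band — the quantity the detector actually thresholds;
* Poisson event counts at per-minute rates, uniform onsets with
  non-overlap enforcement; SOZ contacts receive elevated rates
  (defaults 10 vs 1 spikes/min, 12 vs 2 ripples/min, 8 vs 1 fast
  ripples/min); each fast ripple co-occurs with a ripple with
  probability 0.5;
* the class imbalance of the reference cohort (120 SOZ vs 349 non-SOZ
  contacts) for the tabular generator.

It does **not** simulate ictal activity, artifacts (pulse, movement,
electrode noise), volume conduction between contacts, non-Gaussian
background, or the overlap between physiological and pathological
ripples.  Passing tests therefore demonstrate internal correctness and
end-to-end coherence of the pipeline under its own assumptions — not
clinical-grade performance on real SEEG, where event morphology and
background are far less tidy.

## Problem sizes and numerical conventions

The default test/acceptance problem sizes are chosen to exercise every
stage at desk scale: 10 patients × 10 contacts × 60 s at 2048 Hz for
end-to-end runs, 469-row tables at the reference imbalance for
selection/classification, 100 randomized 50-contact tables for the
normalization oracle.  Other conventions: all times are seconds from
recording start, sample indices are 0-based half-open; EDF output is
16-bit with 1 s records (quantization is the usual EDF precision loss);
entropies are in nats, with all-zero inputs taking the maximum-entropy
convention `log(n)` and degenerate fractal-dimension inputs returning
1; shaft grouping for the bipolar montage is inferred from the
letter-prefix + number naming convention, with an explicit override;
seeds thread through every random stage (background, event placement,
shadow permutations, weight initialization, batch shuffling) so
identical configuration + seed reproduces outputs bit-for-bit.

## Known limitations

* The reference detector stands in for pre-trained deep spike
  detectors; its thresholds were set on the synthetic background and
  would need re-tuning on clinical data.
* The screening detector is a preliminary screen: on real data its
  candidates would normally be vetted further (the amplitude cap is its
  only artifact control).
* The 10th-percentile zeroing step of the ripple normalization is
  sensitive to the per-contact count distribution at small contact
  counts.
* Attention over hidden units is one of several defensible placements
  for an attention block in a tabular MLP; the insertion point is a
  configuration choice, and a no-attention variant is available
  (`use_attention=False`).
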
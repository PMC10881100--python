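# Methods

This note documents the models, parameters and numerical choices behind
`hfonet`, what the synthetic data does and does not emulate, and the known
limitations.

## Detection

The detector is an RMS-threshold scheme of the classical family for
high-frequency oscillations. Per channel and per epoch (default 600 s;
shorter recordings are one epoch), the common-average-referenced signal is
band-passed (zero-phase 4th-order Butterworth, 80–500 Hz) and its sliding
RMS (3 ms window) compared against `mean + 5 SD` of the epoch's RMS.
Supra-threshold intervals closer than 10 ms are merged, then must last
≥ 6 ms and contain ≥ 6 rectified peaks above 3 SD of the rectified epoch
signal. Peaks are counted over the interval padded by 5 ms per side
(`peak_pad`): the oscillation extends beyond the maximal RMS interval, and
counting strictly inside it makes the peak criterion depend on the
threshold crossing rather than on the oscillation. All parameters live in
`DetectorParams`; they are conventional values for this detector family and
deliberately configurable rather than fixed constants.

Epoch-wise thresholding exists so long recordings with nonstationary
background are handled; on the minutes-long synthetic fixtures one epoch is
used.

Artifact redaction uses three parameterized surrogates for the validated
classifiers used clinically:

* **widespread** — accepted detections whose centers co-occur within 10 ms
  on more than half the channels. On montages of only a few channels a true
  network discharge necessarily spans more than half the montage, so tests
  with 3-channel fixtures disable this rule (`widespread_fraction = 1.0`);
  the 0.5 default is meant for clinical-scale montages of tens of channels.
* **sharp transient** — a < 40 Hz excursion beyond 6 SD overlapping the
  event (band-pass filters ring on sharp steps, producing spurious
  high-frequency power).
* **EMG** — 300–500 Hz to 80–200 Hz power ratio above 2 inside the padded
  event window (muscle activity is broadband-high; genuine ripples
  concentrate lower).

Redaction only clears the accepted flag; it never deletes events, never
increases the accepted count, and is idempotent.

## Network construction

Each accepted detection seeds a 100 ms multichannel window centred on the
event (up to 500 events per channel, sampled without replacement, seeded).
Windows are cut from a *once-filtered* recording: common average reference
per electrode group, then a comb of zero-phase notches at the 60 Hz mains
harmonics inside the band, then a zero-phase elliptic band-pass
(order 4, 0.5 dB ripple, 40 dB stopband, 80–500 Hz). Filtering the whole
recording once is numerically identical to per-window filtering away from
window edges and avoids per-window filter transients. The envelope is the
10 ms sliding RMS advanced one raw sample at a time, so lag estimates stay
on the raw 4096 Hz grid — a 10 ms hop would make millisecond lags and the
±1 ms exclusion meaningless.

Pairwise statistics use the Pearson correlation of the two envelopes at
every integer-sample lag (normalized cross-correlation, computed exactly
via windowed cumulative sums). Lags within ±1 ms are excluded as volume
conduction; the maximum lag is 45 ms (just under half the window, leaving
an edge guard). A negative peak lag means the first channel leads. Constant
envelopes have correlation defined as 0 and contribute no lag observation.

* **FCN**: mean peak correlation per pair over event windows, divided by
  the same mean over `background_n` event-free windows (centers ≥ 500 ms
  from any detection, identically preprocessed). Values near 1 mean "no
  more correlated than background". The background-normalization formula is
  this package's own operationalization; the source analysis states only
  that background normalization is applied.
* **LAN**: per ordered pair (i → j), the weight is the mass of a Gaussian
  KDE of the pair's peak-lag distribution on the i-leads (negative) side,
  restricted to lag regions where the bootstrap 95 % pointwise *lower*
  band exceeds the uniform null density 1/(2·max_lag). Bandwidth defaults
  to Silverman's rule (overridable in ms); the bootstrap (default 1000
  resamples) is computed by multinomial reweighting of one precomputed
  kernel matrix, so it is exact, fast and seeded. Pairs with fewer than 5
  lag observations fall back to plain side fractions — a confidence band
  around a 4-point KDE is noise. By construction the two directions of a
  pair are disjoint masses of one density, so their sum is ≤ 1.
* **uLAN / fLAN**: `uLAN[i,j] = max(LAN[i,j], LAN[j,i])` (symmetric);
  the fLAN carries each ordered pair's lead-direction weight (the LAN
  weights themselves), feeding outcloseness.

**Edge normalization.** Whether ordinal-rank normalization applies to edge
weights or only to the downstream per-channel centralities is genuinely
open in the source material. This package computes centralities on raw
edge weights by default and rank-normalizes the *centralities* (which the
ranking step always does). Reason: on small or sparse networks, converting
m near-equal edges to ranks spreads them across the full unit interval —
manufacturing contrast that is not in the data — and under the conventional
0..m−1 scheme the weakest edge receives weight 0, which deletes it from
every shortest-path computation. On a 3-channel planted chain this cost the
true source its top outcloseness rank in roughly half of replicates, with
raw weights recovering it in all. The edge-rank path remains available
(`NetworkParams.rank_normalize = True`) and maps ranks to (1..m)/m so the
weakest present edge keeps positive weight (zero is reserved for absent
edges).

## Centrality

Eigenvector centrality is power iteration on `W + cI` with `c` the maximum
row sum — the shift guarantees a strictly dominant eigenvalue on
bipartite-like graphs without changing eigenvectors — to relative tolerance
1e−10 (max 10⁴ iterations), returning the nonnegative unit-norm principal
eigenvector. All-zero networks return uniform scores with a warning rather
than failing, so degenerate synthetic cases don't abort pipelines.

Outcloseness converts weights to distances `d = 1/w` (strong connection =
short distance) and uses the Wasserman–Faust form
`(r/(N−1)) · (r/Σd)` with `r` the number of reachable nodes — bounded and
well-defined on disconnected forward networks, unlike the raw inverse
total distance; nodes that reach nothing score 0.

Ordinal rank normalization maps the lowest value to 0 and the highest to
N−1, divided by N−1; ties break by channel-label order, which makes every
ranking deterministic and permutation-equivariant.

## Features

* SOZ resection % = 100·|SOZ ∩ RV|/|SOZ| (undefined for an empty SOZ);
  surgery is *definitive* at ≥ 80 %.
* SOZ strata subset sizes use ⌈fraction · |SOZ|⌉ with a floor of one
  channel, so small SOZs always yield nonempty strata.
* CReP(X): n_CReP = ⌈N·X/100⌉ top-ranked channels intersected with the RV,
  divided by n_CReP. Boundary ties are resolved by the ranking's label-order
  policy, not fractional credit — reproducibility over elegance. Its
  maximum is min(|RV|, n_CReP)/n_CReP.
* Engel mapping: I → Class-1, III/IV → Class-3+, II held out of classifier
  training and scored separately against every fold model.

## Outcome model

Gaussian naive Bayes (scikit-learn) with per-class empirical priors and a
variance floor of 1e−9 × the largest feature variance, wrapped in an
explicit leave-one-out loop; the held-out posteriors (sorted back to input
order, so results are row-order invariant) feed all discrimination
statistics. The default feature set is the four CReP30 values.

* AUC is the Mann–Whitney probability with ties counted ½.
* The Hanley–McNeil interval uses the closed-form variance with
  Q₁ = A/(2−A), Q₂ = 2A²/(1+A); bounds are deliberately not clamped to
  [0, 1] — the normal approximation extends past 1 for strong AUCs at
  small n, and clamping would hide that.
* The AUC null test permutes labels without replacement (one-sided,
  add-one continuity); the PPV comparison permutes by swapping the two
  rules' predictions within patient (two-sided); both are seeded.
  Permutations with an undefined PPV contribute a statistic of 0.
* Hotelling T² uses the pooled covariance and the exact F transform
  (requires n − 2 > d; smaller cohorts report the omnibus test as absent);
  per-feature two-tailed t-tests run only when the omnibus p < α.
* Calibration uses 5 equal-width bins — the intended cohorts have ~17
  patients, and more bins would mostly be empty.

**Known bias.** The pooled leave-one-out AUC is *conservative* at small n:
each held-out patient's own class loses one training member, which
systematically depresses that patient's posterior, so under a
label-permutation null the pooled AUC averages well below 0.5 (≈ 0.3–0.4
at n = 17 with a 12/5 split; verified against an independent hand-rolled
naive Bayes with both empirical and uniform priors and both ML and
unbiased variances). Observed AUCs from this pipeline therefore understate,
never overstate, discrimination — and null calibration of the pooled AUC
itself should not be expected.

## Synthetic data

`make_recording` emulates: 1/f ("pink") background noise per channel via
spectral shaping (matching broadband EEG background so band-passed RMS has
realistic variance); Gaussian-windowed sinusoidal bursts (the simplest
waveform whose envelope peak defines an unambiguous onset) propagating
along a hidden directed graph with per-edge lags ≥ 1 ms (so true
propagation survives the ±1 ms exclusion) and multiplicative attenuation;
Poisson discharge emission per root source (or an exact per-source count
for fixtures) and independent Poisson solitary bursts per channel; and
optional sharp-transient, EMG-band and global artifacts. Burst onsets are
quantized to the sampling grid, so per-discharge onset differences equal
edge lags within one sample.

Default study conditions: 4096 Hz sampling, 80–500 Hz events of 20–80 ms
(default 150 Hz, 50 ms), pink-noise SD 10 µV with default burst amplitude
80–120 µV (8–12 × background SD, "high SNR" in the tests). No background
spectra or HFO SNR distributions are characterized for real patients, so
these ranges are chosen for testability, not clinical fidelity. Not
emulated: realistic seizures, electrode geometry, volume-conduction
forward modelling, state-dependent HFO rates, or realistic artifact
morphology — so passing tests demonstrate correctness of the pipeline's
inference on its stated generative model, not clinical performance.

`make_feature_cohort` emulates the cohort level directly: per patient, a
latent "true epileptogenic importance" (enrichment δ on SOZ channels plus
small noise) generates four noisy measured rankings (standard normal plus
δ on SOZ channels; at δ = 0 the rankings are exchangeable with respect to
the SOZ), a resection mixing top-latent channels (per-patient quality drawn
from `resection_quality`) with random ones, and an outcome drawn from a
logistic link on the *true* CReP30 overlap — the link never sees the
measured rankings, so measured-feature separation must be earned through
the enrichment. A residual class separation exists even at δ = 0 because
larger resections raise both the true and the chance measured overlap;
this resection-size confound is clinically realistic and is why the
null-classifier test sets the link slope to 0 rather than δ to 0.

Problem sizes used in the test suite (chosen to exercise every code path at
interactive cost): 3-channel, 30 s recordings with 25 planted discharges
for directionality recovery (50 seeded replicates); cohorts of 20–40
patients with 20–60 channels; 200 replicates for classifier nulls; 2000 for
the Hotelling type-I calibration.

## I/O

Recordings interchange as 16-bit EDF with one-second data records and a
symmetric physical range from the per-channel extrema (round-trip error
bounded by half a quantization step); reading goes through mne. Tables are
CSV (`label,group,soz,resected`; event lists; adjacency matrices with a
JSON sidecar), configuration and reports JSON. All times are seconds from
recording start; intervals are half-open `[start, stop)`; channel labels —
not indices — appear in all files.

## Limitations

* The LAN significance rule (bootstrap lower band vs. uniform null) and the
  FCN background normalization are this package's documented constructions;
  other operationalizations of "lag-asymmetry likelihood" and "background"
  are possible and would shift edge weights, though not the tested
  qualitative recoveries.
* The artifact redactors are simplified surrogates for validated clinical
  detectors and are tuned for the synthetic artifact morphologies.
* Clinical performance claims (patient-level AUC, PPV) require clinical
  recordings, which this package does not ship; nothing here should be read
  as reproducing patient-level results.
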
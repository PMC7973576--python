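# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the order the pipeline applies them.

## Acquisition model

Recordings are integer ADC counts, one column per channel, at a sampling
frequency of 1 kHz with 10-bit resolution by default. The count→voltage
mapping uses the symmetric single-supply convention

    mV = ((c / 2^n) − 0.5) · VCC / G · 1000

with VCC = 3.3 V and front-end gain G = 11,000, so mid-scale (512 counts)
is 0 mV and the full-scale input range referred to the electrodes is
±VCC/(2G) = ±0.15 mV. The acquisition hardware family this emulates does
not publish a canonical mapping; the convention is configurable per channel
(`ChannelSpec.vcc`, `ChannelSpec.gain`) and is *not* asserted to be the one
any particular vendor uses. Streaming throughput is `fs · frame_bytes · 8 /
1000` kbit/s — 56 kbit/s for 7-byte frames at 1 kHz, the maximum the
four-channel configuration requires.

The on-disk format (three `#` header lines, the middle one JSON, then a TSV
integer body) was chosen for human readability and bit-exact round-tripping;
`vcc`/`gain` arrays are carried in the header so a written recording reads
back equal. One file per device; pairing is the pipeline's job, not the
format's.

## Synthetic data: what it emulates, and what it does not

The generator produces the *study conditions* the pipeline is designed for:
5-minute two-device sessions (device A: reference ECG + LED; device B: 1–4
dry-electrode channels + luminosity sensor), resting heart rate defaulting
to 75 BPM (mid 60–100 BPM resting band), 10-bit quantization through the
transfer function above, and an inter-device offset of a few hundred
samples.

* **RR structure.** NN intervals follow a stationary AR(1) process whose two
  parameters are fixed in closed form by the SDNN/SDSD targets
  (φ = 1 − SDSD²/(2·SDNN²), innovation variance SDNN²(1−φ²)); defaults
  SDNN 50 ms, SDSD 30 ms are ordinary resting values. AR(1) was chosen
  because it is the simplest process for which both targets are exactly
  attainable; it is *not* a model of autonomic regulation, so DFA exponents
  of generated series reflect AR(1) correlations, not physiological ones.
* **Beat shape.** A fixed sum-of-Gaussians P-QRS-T template (P at −170 ms,
  Q/R/S around 0, T at +220 ms; R width σ = 12 ms). Any smooth template with
  a dominant R exercises the detector; real morphological variability
  (respiration modulation, ectopy, electrode-position effects) is not
  simulated, so morphology scores on synthetic data represent a noise floor,
  not clinical variability.
* **Amplitude.** R peak defaults to 0.1 mV at the electrode, roughly two
  thirds of the ±0.15 mV full-scale range. A larger nominal amplitude would
  clip at the ADC rails on every beat under this transfer function.
* **Noise model.** White Gaussian measurement noise (default 0.003 mV RMS,
  ≈10 counts), sinusoidal baseline wander (0.01 mV at 0.3 Hz), and
  contact-loss episodes that clamp the experimental channel at an ADC rail —
  the signature of a saturated front end. Episode placement uses one episode
  per equal time slot (uniform within the slot), keeping the episode count
  exact and windows disjoint. Dry-electrode noise is not characterized per
  electrode texture anywhere we could calibrate against, so `noise_rms` is
  an exposed parameter rather than a claimed measurement.
* **Sync pulses.** Rectangular pulses appear on the LED channel and, delayed
  by the configured offset, on the luminosity channel. Default width is
  auto-sized to ≈8% duty cycle so the pulse level is visible to the
  percentile-based threshold (below ~5% duty the 95th percentile of the
  channel equals its baseline and onset detection is undefined by design).

Passing tests on this generator demonstrate that the pipeline's *mechanics*
are correct (alignment, detection, matching, statistics); they do not
certify performance on real dry-electrode recordings, whose artifacts are
richer.

## Synchronization

Pulse onsets are rising edges above the midpoint of the channel's 5th and
95th percentiles, with a 100 ms refractory period. The inter-device offset
is the median of greedily matched onset differences (B − A), and the
residual jitter their median absolute deviation. The median tolerates a
missed or spurious pulse, which whole-channel cross-correlation would not,
since apart from the pulses the two channels carry unrelated signals.
Alignment trims both streams to the common support; no sub-sample
interpolation or clock-drift correction is attempted.

## Conditioning and beat detection

The digital band-pass is a 301-tap (order 300) Hamming-window FIR over
3–45 Hz. At 1 kHz this design's transition band (~11 Hz) is wider than the
3 Hz lower edge, so the raw windowed design would leak ≈20% of DC per pass;
the taps are therefore re-centred to sum exactly to zero, which nulls DC,
brings the 0.5 Hz gain to 0.017 (−35 dB) and leaves the passband essentially
untouched (1.004 at 10 Hz, 0.99 at 40 Hz). Filtering is applied
forward-backward (zero phase) so R-peak latencies are unbiased; the analog
[0.5; 40] Hz hardware band is assumed applied upstream and is emulated only
implicitly by the generator's band-limited content.

R peaks come from an implementation of Hamilton's open-source detector
rules: absolute first difference, 80 ms moving-average integration,
candidate local maxima classified against an adaptive threshold
`noise + 0.3125·(peak − noise)` maintained from running medians of the last
eight QRS and noise peak heights; 200 ms refractory; T-wave rejection for
peaks within 360 ms of the last QRS with less than half its maximal slope;
search-back at half threshold when no QRS appears within 1.5× the running
mean RR. Detections are snapped to the maximum of the conditioned signal
within ±100 ms, assuming positive-dominant R (Lead-I convention). On clean
synthetic recordings the detector scores 100% sensitivity and positive
predictivity at ±10 ms; real-data performance depends on noise and was not
measurable here.

Beat templates are fixed windows of 200 ms before to 400 ms after each R
(covering P-QRS-T at resting rates); beats without full window support are
dropped and reported. All analyses, including morphology, use the 3–45 Hz
trace; whether a wider band would better preserve P/T amplitudes is a known
open point and the window is configurable.

## Heart-rate comparison

Beats are matched greedily, nearest in time first, each beat used once,
within a 150 ms tolerance (half the minimum plausible RR at 200 BPM).
Δ#QRS = 100 · #exp / #ref is computed on the full series before matching,
so values above 100% (spurious detections) are legal and meaningful.
Instantaneous HR is 60000/RR per interval between consecutive normal beats;
values outside 60–100 BPM are kept but flagged as outside the resting band.
ΔHR is formed over consecutive matched pairs (experimental minus reference —
the sign convention is a documented choice, not a given), reported as mean ±
sample SD (ddof 1). The p-value is a two-sided Welch unpaired t-test between
the two channels' HR distributions.

**SDE.** The signal detection error is the percentage of samples outside the
valid measurement range: samples in runs ≥50 ms clamped at an ADC rail, plus
samples in non-overlapping 1-s segments whose SD exceeds 5× the median
segment SD. The corruption rule is restricted to segments containing no rail
samples so clamp transitions are not double-counted; both the 50 ms minimum
run and the 5× factor are exposed in the function signature. The
"outside/total" orientation is used (a clean channel has SDE 0, a fully
saturated one 100), which is the only orientation consistent with reporting
a best channel at SDE 0. The corruption criterion is this package's
operationalization of "grossly corrupted"; no standard definition exists.

## HRV

SDNN and SDSD are sample standard deviations (ddof 1) of the NN series and
its successive differences; intervals adjacent to an outlier-labelled beat,
or outside 300–2000 ms, are excluded. The Poincaré descriptors follow from
them: SD1 = √(SDSD²/2), SD2 = √(2·SDNN² − SDSD²/2), S = π·SD1·SD2. If the
radicand of SD2 is negative (possible for strongly anti-persistent series),
SD2 clamps to 0 and the ratio is undefined; the identity SD1² + SD2² =
2·SDNN² holds exactly whenever no clamping occurs.

DFA is first order with non-overlapping windows: integrate the mean-centred
series, detrend each window of n beats with a least-squares line, average
the per-window RMS residuals into δ(n), and fit log δ against log n.
α1 is fitted over 4–16 beats and α2 over 16–64, the conventional HRV bands.
First-order DFA is known to overestimate the slope at small window sizes for
weakly correlated data — white noise reads α1 ≈ 0.62 over 4–16 beats — so
the result also carries `alpha_overall`, fitted across the whole 4–64 range,
which is the appropriate single-exponent summary (≈0.5 for white noise,
≈1.5 for a random walk) and is what the scaling-limit tests check.

## Morphology

DMEAN computes each beat's deviation from the mean template, pools the
absolute deviations over all beats and samples into μ_D and σ_D, flags
samples with |D| > μ_D + 0.5·σ_D, and keeps a beat when more than 70% of its
samples are unflagged. Three reading choices were required and are exposed
or documented rather than asserted: the TP denominator is the template
sample count (so the rule works for any window length); the deviation is
compared in absolute value (symmetric excursions); and a 10⁻⁹-relative
guard is added to the bound so numerically identical beats are never
flagged by float rounding. Note the rule's expected behaviour under pure
Gaussian deviations: |D| is half-normal, the bound sits at ≈1.1σ, so the
expected TP is ≈73% — deliberately close to the 70% threshold, which makes
the gate sensitive (on noisy synthetic data roughly half the beats are
kept; on the identity case all are). The threshold is a parameter.

Matched kept pairs are scored with the Pearson correlation coefficient and
RMSE normalized by the reference beat's peak-to-peak range (in %), reported
as per-recording mean ± SD. Range normalization is consistent with NRMSE
values in the tens of percent for imperfect electrodes.

## Problem sizes and determinism

Default analyses use 5-minute recordings at 1 kHz (≈375 beats at 75 BPM);
scaling-limit and recovery checks use 5000-beat NN series, 20 seeds for
detector/DFA checks, 50 randomized synchronization configurations and 1000
t-test replicates — sizes at which the Monte-Carlo bands quoted in the tests
are stable. Every stochastic component draws from a single seeded generator;
the pipeline writes its log without timestamps, so a simulate-mode run is
byte-for-byte reproducible from its seed.

## Known limitations

* The generator's AR(1) RR model and fixed beat template do not reproduce
  physiological nonstationarity, ectopic beats, or texture-specific contact
  physics; results on synthetic data bound mechanics, not field performance.
* The Hamilton detector assumes positive-dominant R peaks.
* No clock-drift correction between devices (offset only).
* Frequency-domain HRV and alternative detectors are out of scope.
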
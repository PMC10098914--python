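# Methods

## Problem and signal model

A photoplethysmogram (PPG) — whether from a contact probe or extracted from
face video ("remote" PPG at typical camera rates of 25 Hz) — carries the
cardiac blood-volume pulse, and breathing imprints itself on that pulse
through three mechanisms:

* **RIIV** (respiratory-induced intensity variation): intra-thoracic
  pressure modulates venous return, producing a baseline oscillation of the
  waveform at the respiratory frequency;
* **RIAV** (amplitude variation): stroke-volume changes modulate the height
  of each pulse;
* **RIFV** (frequency variation): respiratory sinus arrhythmia speeds the
  heart on inspiration and slows it on expiration, modulating beat-to-beat
  intervals.

The package estimates the respiratory rate (RR, breaths/min) from a single
PPG channel by three method families, all ending in the same spectral
read-out: the most powerful periodogram peak inside a respiratory search
band, times 60.

## Estimators

**Pulse morphology (IMS).** Incremental merge segmentation subsamples a
window with stride `m`, computes consecutive-point slopes, and iteratively
deletes the central point of every triplet whose two slopes share a sign;
the survivors are the waveform's turning points, split into pulse maxima and
minima. From them three respiratory waveforms are built — the maxima-value
envelope (RIIV), maximum minus preceding minimum (RIAV), and the
inter-minima tachogram (RIFV) — each passed through the artifact-reduction
operator Π (below). The three per-waveform RR estimates are fused as their
mean (`RR_avg`) and median (`RR_median`); a third fusion (`RR_PCA`) takes
the first principal component of the standardized waveform stack as a fused
respiratory waveform. The principal component is computed by SVD *without*
re-centring across the three channels: each series is already zero-mean in
time, and removing the ensemble mean would remove the shared trend that the
fusion is meant to extract.

**Empirical mode decomposition (EMD).** Iterative sifting — cubic-spline
envelopes through the maxima and minima, subtraction of the envelope mean —
extracts intrinsic mode functions until the normalized squared change
between consecutive candidates falls to 0.1 (with an ε = 1e−12 guard on the
denominator), at most 50 iterations per mode and at most four modes, or
until the residual is monotone or has fewer than two maxima or minima.
Envelope splines are fitted after mirror-extending the outermost two extrema
about the window edges. Each IMF yields an in-band RR estimate; `RR_EMD` is
the estimate whose spectral peak carries the most power (a max-frequency
rule is selectable, but power is the default because a frequency rule
systematically favours high-frequency artifacts).

**Singular spectrum analysis (SSA).** The window is lag-embedded into an
L × (M−L+1) Hankel trajectory matrix (default L = 17 samples), decomposed by
SVD into rank-one elementary matrices, and each is mapped back to a series
by anti-diagonal averaging. No component grouping is applied; the first
three components feed per-component RR estimates and `RR_SSA` takes the one
with the greatest peak power, mirroring EMD. EOF signs are fixed by making
each left singular vector's largest-magnitude entry positive, so results are
deterministic.

**Artifact reduction Π.** Π(x) = Deriv(Spline(x)): a cubic spline (not-a-knot
ends) through the points of a series — uniform or beat-event — whose
analytic first derivative is evaluated on a uniform 8 Hz grid.
Differentiation suppresses slow baseline trends and the spline provides the
uniform resampling that beat-event series need before spectral analysis.
The respiratory band lies below 1 Hz, so an 8 Hz grid leaves ample margin.

## Pipeline

Per record: band-pass filter (zero-phase Butterworth; forward–backward so
that pulse timing is undistorted), segment into sliding windows (default
30 s length, 1 s shift), run the selected method per window, post-process
with Π, pick RR in an HR-adaptive band, and aggregate per record as the
median of defined window estimates. Undefined windows (no pulses, too few
beats, no in-band peak) are logged and skipped, never fatal.

Filtering is applied once to the whole record before windowing; with
zero-phase filters this is equivalent to per-window filtering away from the
record edges and considerably cheaper.

Two pre-filter bands are used. The mode-decomposition methods (EMD, SSA)
receive the 0.18–1.0 Hz band of 4th order. For IMS that band would destroy
the cardiac pulses the segmentation needs, so IMS receives a configurable
wider band, default 0.1–1.5 Hz: the lower edge keeps the RIIV baseline, and
the upper edge passes the cardiac fundamental up to 90 beats/min while
excluding the higher-frequency content (diastolic-lobe structure, broadband
noise) that splits pulses into spurious extrema. Both bands are
configuration parameters.

**HR-adaptive respiratory band.** The heart rate is the periodogram peak in
0.7–3.0 Hz, accepted only if it is a local maximum of the full spectrum and
at least 5% of the global peak (leakage side lobes of a strong respiratory
tone are local maxima too, but orders of magnitude weaker). With HR defined
the RR search band is [0.1, min(0.6, HR/2)] Hz — below the first cardiac
harmonic, capped at 36 breaths/min; otherwise the fixed screening band
[0.1, 0.5] Hz is used.

**Beat-timing refinement.** Respiratory sinus arrhythmia modulates beat
intervals by only a few percent of the beat period — about 40 ms at resting
rates, which equals one sample at 25 Hz. Extremum times quantized to the
sample grid would therefore bury the tachogram in quantization noise. Two
refinements address this, leaving the *set* of detected extrema untouched:

1. every extremum's time/value is interpolated by a least-squares parabola
   over a ±0.12 s neighbourhood of strided points;
2. for the tachogram only, extrema are re-timed on a cardiac-narrowband
   version of the window, band [0.7·HR, HR + 0.65] Hz (order 2, zero-phase).
   The band is asymmetric deliberately: noise just below the cardiac line
   (nearest the respiratory band) is what jitters trough times, so the lower
   side is tight; frequency modulation at respiratory rate f puts sidebands
   at HR ± f, and the carrier plus the intact upper sideband suffice to
   preserve the timing modulation, so the upper side is wide enough for any
   in-band f.

**Periodogram.** Rectangular window, mean removal, zero-padding to 4× the
series length so the frequency grid does not quantize RR (grid step
≈ 0.008 Hz for a 30 s window at 8 Hz).

## Quality screen for respiratory references

A reference recording is filtered to 0.1–0.5 Hz (2nd-order Butterworth,
zero-phase), normalized to [−1, 1], and reduced to peak/trough statistics
with a 1 s minimum extremum separation (half a period at the band's upper
edge). σ₁ is the standard deviation of peak-to-peak intervals in seconds,
σ₂ the standard deviation of trough heights in normalized units. A
recording is rejected when shorter than 30 s, when σ₁ > 1 s, or when
σ₂ > 0.2. Extrema within 3 s of the record edges are excluded — the
zero-phase filter settles there — and the filter is reflection-padded over
three periods of its low cut-off, without which edge transients alone
produce σ₂ ≈ 0.1 on a perfectly clean sinusoid. The σ₁ threshold's unit is
taken as seconds, the only scale on which a dispersion of 1 is a meaningful
breath-interval irregularity.

## Synthetic test bed

`generate_ppg` builds records with all three mechanisms under control:
instantaneous heart frequency f_h(t) = f_heart·(1 + a_rifv·sin(2π f_resp t))
integrated analytically to place beats at integer phase crossings; each beat
contributes an asymmetric two-lobe template (systolic Gaussian of width
0.08 s plus a diastolic lobe of relative height 0.4, width 0.25 s, delayed
0.25 s); per-beat amplitudes carry the RIAV factor, an additive baseline
sinusoid carries RIIV, and white Gaussian noise is added at a configurable
SNR defined against the pulse train's RMS. A matched respiratory reference
(sinusoid at f_resp, 1000 Hz) accompanies each record. Defaults are the
study conditions: 25 Hz PPG, 72 beats/min, 15 breaths/min, depths
0.3/0.3/0.05, 10 dB SNR, 60 s.

`generate_corrupted_respiration` exercises the quality screen. Breath-cycle
lengths are drawn from a left-truncated normal whose post-truncation
standard deviation equals the `jitter_s` parameter exactly (naive clipping
at the resolvability floor would silently destroy a third of the requested
dispersion), with cycles running peak-to-peak so drawn intervals are
precisely what σ₁ measures. Trough depths are encoded as per-cycle cosine
amplitude about a zero cycle mean: a depth perturbation of the cycle mean
would be removed as baseline wander by the screening band-pass before the
troughs are measured, whereas amplitude modulation survives in the
sidebands.

What the simulator does **not** model: realistic pulse morphology
(dicrotic notch physiology), motion artifacts beyond additive white noise,
non-stationary respiratory rates, or the video-to-PPG extraction chain.
Passing tests demonstrate that each algorithm recovers the mechanism it
targets under controlled modulation and noise — not field performance on
camera data.

## Evaluation machinery

MAE and RMSE over per-video paired estimates; Bland–Altman agreement with
bias, 1.96 σ limits of agreement and an OLS slope of differences on means
(proportional bias); a Shapiro–Wilk/Levene gate that routes any normality
rejection to the nonparametric branch; the Friedman omnibus test on
within-video ranks (midranks on ties, rank 1 = smallest error, so lower
average rank = better estimator); Nemenyi pairwise p-values from the
Studentized range with infinite degrees of freedom; and the critical
difference CD = q_{α,k}/√2 · √(k(k+1)/(6N)) for rank diagrams.

The robust effect size between two error samples is the difference of
medians over the pooled consistency-scaled median-absolute-deviation
(1.4826·MAD per sample, pooled as a variance-weighted average), labelled
negligible / small / medium / large at |γ| thresholds 0.2 / 0.5 / 0.8.
These thresholds reproduce every published (γ, label) pair we checked.
Median confidence intervals are 95% bootstrap percentile intervals with
2000 seeded resamples.

## Problem sizes used in the test suite and acceptance script

Parameter recovery runs 80 s records (51 overlapping 30 s windows) per grid
cell at 10 dB SNR; statistical calibration uses 200 null replicates at the
study shape (209 × 14); the quality-screen jitter experiment uses 300 s
records (~72 breaths), where the sample-std estimator of breath-interval
dispersion is stable — at 60 s (~14 breaths) the rejection probability is
capped near 80% by sampling variability alone, a property of the estimator
rather than of the screen.

## Known limitations

* The EMD estimators are noise-sensitive: at 10 dB broadband SNR the first
  modes lock onto in-band noise and only clean recordings place the
  respiratory mode reliably in IMF2/IMF3. This matches the method's known
  mode-mixing behaviour and its relative ranking in the literature.
* `RR_EOF3` and `RR_IMF1` usually track cardiac or noise content rather
  than respiration; they are reported because the comparison framework
  needs them, not because they are good estimators.
* The σ₁ screen threshold is interpreted in seconds; recordings at extreme
  breath rates would deserve a rate-relative threshold.
* Event-series resampling (Π) assumes at least four beats per window;
  windows with fewer are skipped rather than extrapolated.
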
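# Methods

`nf1eeg` implements an EEG oscillatory analysis of resting state and visual
n-back working-memory recordings for a two-group comparison (adolescents
with neurofibromatosis type 1, NF1, vs. typically developing controls),
together with a synthetic cohort generator that provides ground truth for
every stage. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic validation does and does not
show.

## Analysis model

### Preprocessing

Continuous 512 Hz, 64-channel (10-10) recordings with HEOG/VEOG/mastoids
are processed as: re-reference to averaged mastoids; 0.1 Hz high-pass;
downsample to 256 Hz; profile low-pass (resting 200 Hz, task 120 Hz); 48-52
Hz band-stop; epoching (task: 0-1900 ms from stimulus onset; rest:
non-overlapping arbitrary 1900 ms epochs, eyes-open and eyes-closed
concatenated) with per-channel mean-centring over the full epoch.

Filters are zero-phase FIR (windowed sinc, odd length, centre-applied).
The high-pass uses a transition band of twice the cutoff so the kernel
stays manageable at 0.1 Hz; the -6 dB point sits at the cutoff. The
downsampler is a polyphase decimator whose anti-alias filter bounds content
at the new Nyquist; because of that, a low-pass edge above 0.95x Nyquist
(the resting profile's 200 Hz at a 128 Hz Nyquist) is a no-op and is
skipped with a log note. The notch is a band-stop with -6 dB edges at
46/54 Hz, verified in tests to attenuate 50 Hz by >= 20 dB while leaving
40 Hz within 1 dB.

Ocular cleaning extracts 32 extended-infomax components from scalp
channels only (persistently noisy channels, TP7 by default, temporarily
omitted), after PCA whitening to 32 dimensions. A component is removed
when its absolute temporal correlation with VEOG/HEOG or spatial
correlation with the blink topography is *uniquely high*: above the median
plus 4 robust SDs (MAD) of the 32 values **and** above an absolute floor.
The floor is 0.3 for the temporal correlations (brain components correlate
with EOG near zero) and 0.7 for the spatial correlation, because broad
frontal oscillatory topographies legitimately correlate up to ~0.5 with
the focal blink projection; both floors are config-exposed. Baseline
mean-centring is re-applied after cleaning.

Amplitude rejection is two-pass: epochs exceeding the threshold (rest 200
uV, task 120 uV) on any scalp channel are rejected; channels exceeding on
> 20% of epochs are declared bad; rejection is re-run ignoring bad
channels, which are then reconstructed by spherical-spline interpolation
(Perrin splines, m = 4, 50 Legendre terms, regularization 1e-5). Data are
then re-referenced to the common average over scalp channels. A
participant enters an analysis only with >= 15 valid epochs in every
condition of that analysis (task epochs must also carry a correct
response); all scalp channels bad is a fatal per-participant error.

### Spectral power

Power is a single-window estimate: Hann taper over 900-1900 ms (256
samples at 256 Hz, hence exactly 1 Hz bins), squared magnitude with
amplitude compensation so a unit sinusoid yields mean-square power 0.5 at
its bin independent of window length or zero-padding. Power is
log10-transformed per epoch *before* averaging over epochs; a regression
test keeps this order honest because it differs from average-then-log by a
Jensen gap. Band power is the mean of log power over in-band bins
(inclusive integer bounds: delta 1-3, theta 4-7, alpha 8-11, beta 12-29,
low-gamma 30-47, high-gamma 53-100 Hz; 48-52 Hz is deliberately uncovered,
matching the notch) and over the channel set (all scalp channels, or the
Fz/F1/F2 mid-frontal ROI). These are absolute, not relative, powers.
Task-specific power is log(task) - log(eyes-open rest) per band; its sign
is interpretable only as relative modulation.

### Peak alpha frequency

The PAF spectrum uses the full 1900 ms epoch zero-padded to 4 s (0.25 Hz
bins). The aperiodic background is a quadratic in log10 frequency fitted
over 1-40 and 55-100 Hz, omitting the loose alpha range (6.5-13.5 Hz) and
the notch region (48-52 Hz); the residual is smoothed with a Gaussian
kernel (SD 2 bins = 0.5 Hz, truncated at +/-4 SD) and the PAF is the
residual's arg-max over 6.5-13.5 Hz at Pz. Estimates are flagged
`needs-review` when the maximum sits at a range boundary or the smoothed
residual rises strictly monotonically toward the range edge in the
half-range containing the maximum (the ascending-beta / descending-delta
failure modes); manual overrides are applied only explicitly and are
recorded in the estimate, never silently.

### Theta phase coherence

Task epochs are spatially filtered with a spherical-spline Surface
Laplacian (m = 4, 10 Legendre terms, regularization 1e-5) to suppress
volume conduction. Instantaneous phase comes from complex Morlet wavelets
(4 cycles, Gaussian SD 4/(2 pi f)) at 4, 5, 6 and 7 Hz; the kernel is
truncated at +/-2.5 SD, which keeps the 4 Hz half-support (~398 ms) inside
the 400 ms guard band between the 1500 ms window end and the 1900 ms epoch
end — the implementation asserts this rather than assuming it. Inter-site
phase clustering over n trials at time t is |n^-1 sum exp(i(phi_x -
phi_y))|. It is computed for all 27 mid-frontal (F1/Fz/F2) to parietal
(P3/P5/P7, P1/Pz/P2, P4/P6/P8) channel pairs and averaged in a fixed,
regression-tested order: time window (900-1500 ms) -> frequencies ->
channel pairs, giving one estimate per region pair (ML/MM/MR) and load.
The eyes-open resting baseline is computed identically (arbitrary rest
epochs acting as trials, Laplacian included) and subtracted; the adjusted
value may be negative and is never clipped.

### Statistics

The mixed ANOVA (one between factor, one or two within factors) is
computed by the classical univariate error-stratum decomposition with
sum-to-zero coding, which yields Type III hypothesis sums of squares under
unbalanced group sizes; it reproduces R's `car::Anova(type = 3)`
univariate repeated-measures table and, on balanced data, a brute-force
cell-means oracle to 1e-10. For within factors with more than two levels
the conventional uncorrected F and degrees of freedom are reported, with
the Greenhouse-Geisser epsilon and corrected p alongside as a diagnostic.
Partial eta squared satisfies eta_p^2 = F df1/(F df1 + df2) on every row.
Paired t-tests report Cohen's d = mean/SD of differences = t/sqrt(n).
Independent correlations are compared with the standard two-sample Fisher
r-to-z statistic z = (atanh r1 - atanh r2)/sqrt(1/(n1-3) + 1/(n2-3)).
Multiple comparisons use Benjamini-Hochberg FDR at 5% within each family.
Extreme outliers are values outside Q3 + 3 IQR / Q1 - 3 IQR with quartiles
by linear interpolation (config-relevant because the flag boundary depends
on the quartile method); when any are flagged the analysis is re-run
without those subjects and both results reported.

## Synthetic cohort generator

Each subject's recording is a 1/f^chi background (chi = 1, 2.5 uV RMS per
channel, independent across channels) plus per-band oscillations
synthesized as narrowband-filtered Gaussian noise — not pure sinusoids —
so instantaneous phase is non-degenerate and wavelet phase estimation is
genuinely exercised. Each band has a centre frequency, bandwidth, RMS
amplitude, smooth scalp topography, and an eyes-closed power gain; the
defaults (delta 9, theta 8, alpha 8, beta 2.5, low-gamma 1.2, high-gamma
1.0 uV; closed gains 1.5/2.2/8.0/1.2/0.3/0.2) were chosen once so that the
measured eyes-closed reactivity pattern and the recoverability of injected
log-power offsets match the group-level structure the analysis is built to
detect: low frequencies and alpha rise with eyes closed, gamma falls, and
a +0.4 log10 injected offset is recovered by the full pipeline to within
about 15-20% (the oscillation must dominate the in-band background for an
amplitude offset to survive as a band-power offset).

NF1-like subjects add group offsets — +0.4 log10 delta, +0.6 log10 theta
and a -1.3 Hz alpha-centre shift by default, anchored to the reported
group means of the targeted study design — on top of between-subject variability (log-power offsets
N(0, 0.3), alpha centre N(0, 0.8 Hz)). Per-subject seeds derive
deterministically from the master seed via seed-sequence spawning, so
cohorts are reproducible and per-subject outputs are independent of cohort
composition.

Frontoparietal theta coupling injects a shared narrowband theta source
into the mid-frontal seed and, phase-lagged (Hilbert shift) and mixed with
an independent theta component, into each parietal region; the mixing
ratio equals the von Mises mean resultant I1(kappa)/I0(kappa), so the
injected ISPC approximates that closed form. A separate two-channel
generator draws per-trial phase differences directly from von
Mises(lag, kappa) as the exact ground truth for the ISPC estimator.

Artifacts: blinks are 300 ms raised-cosine positive deflections on VEOG
with a frontal scalp projection decaying with distance from the eyes
(Gaussian in chord distance, VEOG weight 1 by convention); saccades are
square-wave deflections on HEOG with a weak lateralized scalp leak.
Default rates (0.15 blinks/s, 0.08 saccades/s) are plausible but are a
testability choice, not a fit to data. The n-back event stream follows
the four-block 1/2/2/1-back structure with 100 trials and 25 targets per
block, 2.5 s nominal trial period with +/-100 ms jitter in 17 ms steps,
log-normal response times (median 601 ms, sigma 0.29), 95% hit rate and 2%
false-alarm rate; correctness is reconstructed from the event stream at
epoching time, mirroring how a real event file would be used.

### What the generator does not emulate

No biophysical head model or realistic volume conduction (mixing is
topography- and distance-based only), no heteroscedastic or non-Gaussian
between-subject structure, no age dependence of any EEG measure (ages are
drawn independently, so age correlations are null by construction), no
comorbidity subgroups, no non-ocular artifact classes. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it assumes, under that structure — not that the pipeline is robust to real
recordings' full complexity.

## Problem sizes used in validation

The session defaults are the full study structure (2.5 min per rest
condition, four 100-trial blocks). The validation studies run scaled-down
versions chosen once: group-difference recovery and null type-I use 32 s
per rest condition (16 arbitrary epochs, one above the inclusion minimum),
n = 16/14 subjects, 20 seeded replicates per condition, with artifacts and
ICA disabled (ocular cleaning is validated separately on recordings with
known injected blinks; disabling both together leaves band power
unchanged, as the cleaning-chain test shows). PAF recovery uses 100
subjects with 30 s of eyes-closed rest and alpha centres uniform on
7.5-12.5 Hz. ISPC identities and kappa recovery use direct phase-series
construction (exact) and the two-channel generator at n = 500 trials
(wavelet path).

## Known limitations

* The EDF writer quantizes to 16 bits with physical bounds rounded to 0.01
  uV; round trips are exact only to that quantization.
* The mixed ANOVA supports at most two within-subject factors and one
  between-subject factor — exactly the designs used here.
* The 1/f adjustment is a quadratic in log-frequency, not a full
  periodic/aperiodic decomposition; spectra with strong knees could bias
  the alpha residual.
* Wavelet truncation at +/-2.5 SD slightly broadens spectral leakage
  relative to an untruncated Morlet; the constant-phase and slope tests
  bound the practical effect on phase.
* The standard two-sample Fisher z is reported for correlation
  comparisons; alternative variants (e.g. pooled-n or dependent-correlation
  forms) are not implemented.
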
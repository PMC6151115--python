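# Methods

`cholosc` re-implements, as a tested pipeline, a standard analysis of
carbachol-induced network oscillations in organotypic hippocampal cultures
recorded on planar multielectrode arrays (MEAs): preprocessing, sliding-window
multitaper spectral estimation, prominence-based oscillation detection with
band categorization, and binomial modelling of per-culture oscillation
occurrence over genotype and days in vitro (DIV).  Because such recordings
are rarely shareable, the package includes a synthetic-recording generator
that reproduces the statistical structure the analysis assumes, so every
stage can be validated against known ground truth.

## Trial structure and preprocessing

A trial is a 60 s multichannel recording: 30 s baseline, a 1 s cholinergic
stimulus (carbachol) at `onset_s = 30`, and the response.  Six trials are
recorded per culture; the first is a carbachol-naive control and is excluded
from every average, leaving five.  Channels carry one hippocampal-area label
(DG, CA3, CA1).

Raw 20 kHz data are decimated to 1 kHz by single-stage polyphase FIR
filtering (anti-alias passband edge at 0.45 x target rate, odd-length
`firwin` design scaled with the decimation factor, group delay compensated),
then high-passed at 1 Hz with an order-4 Butterworth filter.  The high-pass
is zero-phase by default (forward-backward, squared magnitude response):
since all analysis windows are aligned to the stimulus onset, any filter
latency would bias the post-stimulus window assignment.  A causal single-pass
variant is selectable (`zero_phase=False`).  Both stages are linear and
preserve the 2-400 Hz band energy to within 2%.

## Spectral estimation

Time-frequency power is estimated by a short-time Fourier transform with
discrete prolate spheroidal sequence (DPSS, Slepian) multitapers: a 1 s
window shifted by 100 ms over the whole trial, frequencies 1-500 Hz on the
1 Hz grid the window implies.  The +/-2 Hz frequency smoothing is interpreted
as the multitaper half-bandwidth W = 2 Hz, giving time-bandwidth product
NW = 2 and the conventional K = 2NW - 1 = 3 tapers; K is configurable, and
K = 1 agrees with a Hann-periodogram oracle to within 5% band-integrated
power at a peak.  The window count follows floor((T - w)/step) + 1 (591
windows for a 60 s trial); this alignment convention is asserted by tests,
not inherited from any particular toolbox.

The *post-stimulus spectrum* is the mean over all windows starting at or
after the onset (291 windows of a standard trial; the median is available).
It then passes through a strictly ordered chain, recorded in a `stage`
field so no step can run out of order:

1. **1/f correction** — every power value is multiplied by its frequency,
   flattening the 1/f background (a pure pink-noise input comes out with
   log-log slope 0 +/- 0.15 over 2-400 Hz).
2. **Line-harmonic excision** — power within +/-3 Hz of every 50 Hz harmonic
   (ten harmonics reach 500 Hz) is replaced by linear interpolation between
   the boundary grid points; a boundary falling off the grid clips the
   interval and holds the available endpoint flat.
3. **Normalization** — each channel is divided by its own spectrum sum
   (unit-sum spectra within 1e-9).  All-zero channels are flagged inactive
   and excluded from detection rather than raising.

Trials of one culture are averaged element-wise after the naive-trial
exclusion.  By default the *normalized* per-trial spectra are averaged,
which makes trials of different overall power commensurate; averaging the
line-excised spectra first and normalizing once is selectable
(`normalize_before_average=False`) and covered by tests.  For the linear
steps (1) and (2) the per-window versus post-average order is mathematically
immaterial; applying them to the time-averaged spectrum is cheaper.

## Oscillation detection and band categorization

The prominence of a local maximum is the height above the higher of the two
minima found by extending a horizontal line left and right until it crosses
a strictly higher sample or the end of the vector; plateaus count once, at
their center grid point.  The implementation is backed by
`scipy.signal.find_peaks` and is checked for exact agreement against an
independent brute-force walk of this definition on 10^4 random vectors.

A channel is *active* in a band when its best peak inside the band reaches a
prominence of 0.001 normalized units — the level at which a peak becomes a
small but distinguishable bump of a unit-sum spectrum.  Peaks are located on
the full 1-500 Hz normalized spectrum and then attributed to bands, rather
than on per-band slices: at 1 Hz resolution the delta band holds only three
grid points, so slice-local prominence would make band-edge peaks
undetectable.  Per channel the highest-prominence peak inside the band is
used (prominence, not height, mirrors the thresholding logic; ties break to
the lower frequency).

The four canonical ranges are scanned automatically: delta [1, 4), theta
[4, 10), beta [10, 30), gamma [30, 100) Hz.  The half-open convention forces
a partition of 1-100 Hz (4 Hz is theta, 10 Hz beta, 30 Hz gamma).  A band is
*present* when at least one channel is active; its frequency is the mode of
the active channels' peak frequencies (equally common values break to the
lowest), and the band label follows the range containing that mode.  This
automated scan replaces the manual, blinded band-range selection of the
original workflow; the manual step only located candidate ranges that were
then categorized into the same four bands, so automation trades a human
judgment for reproducibility.

Peak power is reported relative to the mean power over the inclusive
200-250 Hz reference band (51 grid points) on the frequency-corrected,
line-excised spectrum, per active channel; the band-level summary is the
mean over active channels (the per-channel values are also exported).  The
quantity is invariant to overall spectrum rescaling.

One systematic effect of the x f correction deserves note: for a line-like
oscillation the correction tilts the +/-2 Hz spectral lobe upward, so the
read-out peak sits about one 1 Hz bin above the source frequency.  The
generator defaults account for this (see below).

## Occurrence modelling

Detection runs per hippocampal area, giving one presence row per culture x
area x band.  Areas are collapsed with a logical OR (a culture has an
oscillation if any area does) before the genotype/DIV models are fitted;
pre-collapse tables can include `area` as a factor.

Per band, presence is modelled by maximum-likelihood binomial logistic
regression (IRLS via statsmodels GLM).  DIV enters categorically (three
levels, 7/13/26), matching per-DIV statements of occurrence probabilities;
an ordinal coding can be expressed by passing a numeric column.  The
candidate set for model selection is every term set respecting marginality
— interactions only alongside all their main effects — from the
intercept-only null model to the full factorial (5 models for two factors,
19 for three).  Models are ranked by AIC = 2k - 2 lnL (identity asserted
exactly for every fit); exact ties prefer the smaller model, and the best
model is additionally assessed against the null with a likelihood-ratio
test.  Perfect or quasi-separation and IRLS non-convergence are flagged
(`converged=False`, runaway log-odds beyond 15), never silently returned;
no penalized fallback is fitted — flagged fits are the caller's signal that
the cell counts cannot support the model.

Peak frequency and relative peak power are compared over genotype x DIV by
two-way fixed-effects ANOVA with Type II sums of squares (robust to the
unbalanced cell counts presence-conditioning produces).  Each quantity is a
family of four band-wise tests, so the significance flag uses the
family-wise level alpha = 0.0125.  Degenerate inputs (constant values, no
residual degrees of freedom) yield flagged non-significant rows; an empty
genotype x DIV cell drops the interaction with a warning.  Per-culture
values entering the ANOVA are means over the culture's present areas.

## Synthetic recordings

`generate_recording` sums, per channel: pink (1/f) noise synthesized by
frequency-domain shaping (amplitude proportional to 1/sqrt(f) for
f >= 1 Hz, zero DC, unit RMS, scaled to 20 uV RMS by default), white sensor
noise (2 uV RMS), and line hum shared across channels at 50/100/150 Hz
(10/5/2.5 uV, halving per harmonic so every excision window is exercised).
Each *present* band adds a narrowband oscillation to a configurable fraction
(default one half) of the channels in its active areas, starting at the
stimulus onset with a 0.5 s linear amplitude ramp: by default a 30 uV
sinusoid with random phase; band-pass-filtered Gaussian noise is selectable.
Both waveforms present a single spectral peak — the only property the
detector consumes — which is why no biophysical network model is attempted.

Default band centers are chosen so the *analyzed* peak lands where these
cultures are reported to peak, given the one-bin upward shift of the x f
correction: delta 2 Hz (read out at 3 Hz), theta 6 Hz, beta 20 Hz (~21 Hz),
gamma 40 Hz (~41 Hz).  The default electrode map splits the channels into
three equal contiguous area blocks (DG/CA3/CA1); real area maps come from
photographs of each culture and can be passed explicitly.

Whether a culture expresses a band is drawn once per culture (not per
trial — presence is treated as a stable property of the culture, consistent
with the within-culture averaging design) from a per-band logistic model in
genotype and DIV.  Defaults reproduce the reported occurrence rates exactly:
delta 49%, theta 22%, beta 91% at every DIV, and gamma rising 27% / 62% /
65% over DIV 7/13/26, with no genotype effect.  Identical (config, seed)
reproduces every signal bit-exactly; signals are emitted as float32, which
the HDF5 container round-trips losslessly.

What the generator does *not* emulate: spatial correlation between
electrodes beyond the shared hum, within-culture inter-trial variability of
oscillation expression, the transient application artifact of the real
stimulus, non-stationary or harmonically distorted oscillation waveforms,
and any pharmacology.  Passing tests therefore demonstrate that the
analysis recovers the structure it assumes — not that real recordings meet
those assumptions.

## Validation problem sizes

The ground-truth validation studies are sized to run comfortably on one CPU
while keeping their statistical margins:

* **Prominence oracle** — 10^4 random vectors, lengths 3-500, one fifth
  rounded to force tied plateaus; agreement must be exact.
* **Known-peak recovery** — 100 single-channel 60 s trials, unit 40 Hz
  sinusoid in pink noise at power SNR 10.
* **Detection screen** — 204 cultures (34 per genotype x DIV cell) at
  default amplitudes and trial structure, scaled to 12 electrodes (4 per
  area) and four retained trials per culture instead of the full
  60-electrode / five-trial design.  The averaged-trial count matters:
  single-trial spectra fluctuate enough that background bumps occasionally
  cross the 0.001 prominence threshold, and the threshold's clean behaviour
  is a property of the trial-averaged spectra the design prescribes.
* **Occurrence recovery** — presence-level cohorts (the generator's
  logistic layer) at 200 cultures per cell; 100 replicate cohorts for the
  selection-rate studies.  Full signal synthesis adds nothing here, since
  the detection screen already validates the signal-to-presence map.

## Known limitations

* The detector reports at 1 Hz resolution and one band per canonical range;
  it does not resolve multiple distinct peaks within one band, burst
  timing, or cross-channel phase relationships.
* The spectrum-stage order (correct, excise, normalize) is enforced, not
  configurable; analyses wanting a different order must compose the stages
  manually.
* Separation-flagged logistic fits stay in the AIC ranking (marked
  non-converged); with very small cohorts the ranking should be read
  accordingly.
* The generator's per-culture presence model means the five retained trials
  of a culture are statistically exchangeable; designs that need
  trial-to-trial dynamics are out of scope.
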
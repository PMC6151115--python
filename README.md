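# cholosc

Analysis of carbachol-induced network oscillations in multichannel
microelectrode-array (MEA) recordings of organotypic hippocampal cultures —
and a synthetic-recording generator that gives every stage of the analysis
known ground truth.

Brief cholinergic stimulation (carbachol) makes hippocampal tissue oscillate
in the classic delta (1-4 Hz), theta (4-10 Hz), beta (10-30 Hz) and gamma
(30-100 Hz) bands.  A typical developmental experiment records 60-electrode
MEAs over cultures of two genotypes at several ages in vitro (DIV) and asks:
*which bands occur, in which hippocampal subfield (DG/CA3/CA1), and does the
probability of occurrence change with genotype or DIV?*  This package
implements that full chain for anyone running or re-analyzing such
experiments:

1. **Preprocessing** — decimation of raw 20 kHz data to 1 kHz (anti-aliased
   polyphase FIR) and a zero-phase order-4 Butterworth high-pass at 1 Hz.
2. **Spectral estimation** — short-time DPSS multitaper transform (1 s
   window, 100 ms shift, half-bandwidth W = 2 Hz so NW = 2, K = 3 Slepian
   tapers), 1-500 Hz; post-stimulus averaging; x f correction of the 1/f
   background; +/-3 Hz excision and linear interpolation of the 50 Hz line
   harmonics; per-channel unit-sum normalization; five-trial averaging with
   the carbachol-naive first trial excluded.
3. **Band detection** — per channel, the highest-prominence spectral peak
   per band; channels with prominence >= 0.001 normalized units are active;
   a band is present when any channel is active, at the mode of the active
   channels' peak frequencies; peak power is reported relative to the mean
   200-250 Hz power.
4. **Occurrence statistics** — per-culture presence (areas collapsed by
   logical OR) modelled by binomial logistic regression in genotype and
   categorical DIV; all marginality-respecting candidate models ranked by
   AIC = 2k - 2 lnL with a likelihood-ratio check against the null; two-way
   Type II ANOVA of peak frequency and relative peak power at the
   family-wise level alpha = 0.0125.
5. **Synthetic data** — multichannel trials of pink noise, white noise and
   50 Hz hum plus band-limited oscillations that start at the stimulus
   onset in a configurable fraction of channels per area, with per-culture
   band presence drawn from a logistic occurrence model (defaults: delta
   49%, theta 22%, beta 91% flat in DIV; gamma 27% / 62% / 65% over DIV
   7/13/26).

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Simulate a small cohort, analyze it, and model occurrence — either through
the numbered drivers:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_analyze_cohort.py
python analysis/03_occurrence_recovery.py
python analysis/04_detection_validation.py
```

or via the CLI (`cholosc simulate | analyze | stats | run-all`).  The demo
cohort is 12 cultures (2 per genotype x DIV cell), three 60 s trials each on
a 12-electrode array.  `02_analyze_cohort.py` prints:

```
analyzed 12 cultures (0 failed)
culture-level presence agreement with ground truth: 1.000

detected occurrence per band (collapsed over areas):
band
beta     0.750000
delta    0.833333
gamma    0.333333
theta    0.250000
```

i.e. every band the generator placed in a culture was detected and nothing
else was (agreement 1.000), with this small cohort's empirical rates shown
per band.  `03_occurrence_recovery.py` repeats the statistics at a
realistic scale (200 cultures per cell) and recovers the generating
occurrence model:

```
   quantity  estimate  truth
 gamma_div7  0.280000   0.27
gamma_div13  0.610000   0.62
gamma_div26  0.615000   0.65
...
best gamma model: div
```

— the selected lowest-AIC model for gamma contains DIV (its occurrence
rises with age in vitro), while for the flat bands the null model wins.
`04_detection_validation.py` checks the signal level: pink-noise slope
-1.005 before and -0.005 after the 1/f correction, a 40 Hz sinusoid at
power SNR 10 recovered at 40 +/- 1 Hz in 100% of 100 trials, and
sensitivity/specificity of 1.000/1.000 over a 204-culture screen.

Recordings are exchanged as HDF5 containers (`signal`, `fs`,
`channel_area`, `meta`); all tables are plain CSV; every run writes its
resolved configuration and a log with the seed.

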
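"""Synthetic multichannel LFP generator.

Emulates the statistical structure the analysis pipeline assumes from a
carbachol trial on a 60-electrode MEA: 1/f (pink) background noise, white
sensor noise, 50 Hz line hum with decaying harmonics, and band-limited
oscillatory responses that begin at the stimulus onset in a configurable
fraction of the channels of each hippocampal area.  Whether a culture
expresses a band at all is drawn from a per-band logistic occurrence model in
genotype and days in vitro (DIV), so cohort-level statistics have known ground
truth.

Nothing biophysical is simulated: there are no neurons and no pharmacology,
only signals whose spectra match what the spectral stage expects to see.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import AREAS, BAND_NAMES, BAND_RANGES, Recording, TrialMeta


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class BandSpec:
    """Generative model of one oscillation band.

    amplitude is the sinusoid peak amplitude (or the RMS of the band-pass
    noise variant) in the same microvolt-scaled units as the background.
    ``channel_fraction`` of the channels in ``areas`` carry the oscillation.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float = 30.0
    areas: Tuple[str, ...] = AREAS
    channel_fraction: float = 0.5
    waveform: str = "sinusoid"  # or "noise": band-pass-filtered Gaussian noise

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.waveform not in ("sinusoid", "noise"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not 0.0 <= self.channel_fraction <= 1.0:
            raise ValueError("channel_fraction must be in [0, 1]")


@dataclass(frozen=True)
class OccurrenceModel:
    """Logistic model for per-culture presence of one band.

    log-odds = intercept + div_coefs[div] + genotype_coef * [genotype == KO].
    DIV is coded categorically; unknown DIVs fall back to the baseline level.
    """

    intercept: float
    div_coefs: Mapping[int, float] = field(default_factory=dict)
    genotype_coef: float = 0.0

    def log_odds(self, genotype: str, div: int) -> float:
        eta = self.intercept + dict(self.div_coefs).get(int(div), 0.0)
        if genotype == "KO":
            eta += self.genotype_coef
        return eta

    def probability(self, genotype: str, div: int) -> float:
        return _expit(self.log_odds(genotype, div))

    @classmethod
    def from_probabilities(cls, p_by_div: Mapping[int, float],
                           genotype_coef: float = 0.0) -> "OccurrenceModel":
        """Build a DIV-categorical model hitting given probabilities exactly."""
        divs = sorted(p_by_div)
        base = divs[0]
        intercept = _logit(p_by_div[base])
        coefs = {d: _logit(p_by_div[d]) - intercept for d in divs[1:]}
        return cls(intercept=intercept, div_coefs=coefs, genotype_coef=genotype_coef)


def default_band_specs() -> Dict[str, BandSpec]:
    # Centers chosen so the *analyzed* peak lands where these cultures peak:
    # the multiply-by-frequency correction tilts the +/-2 Hz multitaper lobe
    # of a line upward by about one 1 Hz bin, so a 2 Hz delta source is read
    # out at 3 Hz (the reported stable delta peak) and 20 Hz beta at ~21 Hz.
    return {
        "delta": BandSpec(center_hz=2.0, bandwidth_hz=1.0),
        "theta": BandSpec(center_hz=6.0, bandwidth_hz=2.0),
        "beta": BandSpec(center_hz=20.0, bandwidth_hz=3.0),
        "gamma": BandSpec(center_hz=40.0, bandwidth_hz=5.0),
    }


def default_occurrence_models() -> Dict[str, OccurrenceModel]:
    # Occurrence probabilities reproduce the study's reported rates:
    # delta 49%, theta 22%, beta 91% flat in DIV; gamma rising 27/62/65 %
    # over DIV 7/13/26.  No genotype effect in any band.
    return {
        "delta": OccurrenceModel(intercept=_logit(0.49)),
        "theta": OccurrenceModel(intercept=_logit(0.22)),
        "beta": OccurrenceModel(intercept=_logit(0.91)),
        "gamma": OccurrenceModel.from_probabilities({7: 0.27, 13: 0.62, 26: 0.65}),
    }


def default_area_map(n_channels: int = 60) -> Tuple[str, ...]:
    """Fixed layout: channels split into three equal contiguous blocks
    DG / CA3 / CA1 (the study assigned areas from photographs)."""
    if n_channels % 3:
        raise ValueError("default area map needs n_channels divisible by 3")
    per = n_channels // 3
    return tuple(a for a in AREAS for _ in range(per))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic recording generator.

    Amplitudes are microvolt-scaled: pink/white amplitudes are RMS values,
    hum amplitudes are sinusoid peak values.  Defaults represent a clearly
    oscillating culture over a realistic extracellular background.
    """

    n_channels: int = 60
    fs: float = 1000.0
    duration_s: float = 60.0
    onset_s: float = 30.0
    ramp_s: float = 0.5
    pink_noise_amplitude: float = 20.0
    white_noise_amplitude: float = 2.0
    hum_freq_hz: float = 50.0
    hum_harmonic_amplitudes: Tuple[float, ...] = (10.0, 5.0, 2.5)
    bands: Mapping[str, BandSpec] = field(default_factory=default_band_specs)
    occurrence: Mapping[str, OccurrenceModel] = field(default_factory=default_occurrence_models)
    area_map: Optional[Tuple[str, ...]] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.fs not in (20000.0, 1000.0, 20000, 1000):
            raise ValueError("generated recordings use fs of 20000 (raw) or 1000 Hz")
        if any(a < 0 for a in self.hum_harmonic_amplitudes):
            raise ValueError("hum amplitudes must be >= 0")
        if self.pink_noise_amplitude < 0 or self.white_noise_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for name, spec in self.bands.items():
            if name not in BAND_RANGES:
                raise ValueError(f"unknown band {name!r}")
            lo, hi = BAND_RANGES[name]
            if not (lo <= spec.center_hz < hi):
                raise ValueError(
                    f"{name} center {spec.center_hz} Hz outside its range [{lo}, {hi})"
                )

    def resolved_area_map(self) -> Tuple[str, ...]:
        if self.area_map is not None:
            if len(self.area_map) != self.n_channels:
                raise ValueError("area_map length must equal n_channels")
            return tuple(self.area_map)
        return default_area_map(self.n_channels)


def pink_noise(n_samples: int, fs: float, rng: np.random.Generator,
               n_channels: Optional[int] = None) -> np.ndarray:
    """Unit-RMS 1/f noise by frequency-domain shaping.

    Amplitude proportional to 1/sqrt(f) for f >= 1 Hz, zero below (and at DC),
    with independent Gaussian real/imaginary parts per bin.  Returns one
    vector, or an (n_channels, n_samples) matrix of independent channels.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs >= 1.0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    size = (n_channels or 1, freqs.size)
    spec = shape * (rng.standard_normal(size) + 1j * rng.standard_normal(size))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    x /= np.where(sd > 0, sd, 1.0)
    return x if n_channels is not None else x[0]


def _oscillation(spec: BandSpec, t: np.ndarray, ramp: np.ndarray, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.waveform == "sinusoid":
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(2.0 * np.pi * spec.center_hz * t + phase)
    else:
        lo = max(spec.center_hz - spec.bandwidth_hz / 2.0, 0.1)
        hi = min(spec.center_hz + spec.bandwidth_hz / 2.0, 0.999 * fs / 2.0)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        wave = sps.sosfiltfilt(sos, rng.standard_normal(t.size))
        sd = wave.std()
        if sd > 0:
            wave = wave / sd
    return spec.amplitude * ramp * wave


def draw_active_channels(config: GeneratorConfig, band: str,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample the channel subset that expresses ``band``: a fixed fraction of
    the channels in the band's active areas, without replacement."""
    spec = config.bands[band]
    areas = np.asarray(config.resolved_area_map(), dtype=object)
    pool = np.flatnonzero(np.isin(areas, list(spec.areas)))
    k = int(round(spec.channel_fraction * pool.size))
    if k == 0:
        return np.empty(0, dtype=int)
    return np.sort(rng.choice(pool, size=k, replace=False))


def generate_recording(config: GeneratorConfig, meta: TrialMeta,
                       band_presence: Mapping[str, bool],
                       rng: Optional[np.random.Generator] = None,
                       active_channels: Optional[Mapping[str, Sequence[int]]] = None,
                       ) -> Recording:
    """Synthesize one trial.

    Background (pink + white noise, line hum and harmonics) runs for the whole
    trial; each present band adds its oscillation to its active channels from
    ``meta.onset_s`` on, with a linear amplitude ramp of ``config.ramp_s``.
    Identical (config, meta, presence, seed) reproduces the signal bit-exactly.
    """
    unknown = set(band_presence) - set(BAND_NAMES)
    if unknown:
        raise ValueError(f"unknown band(s) in band_presence: {sorted(unknown)}")
    n_float = config.fs * meta.duration_s
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(
            f"fs * duration must be integral, got {config.fs} * {meta.duration_s} = {n_float}"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    t = np.arange(n) / config.fs
    sig = pink_noise(n, config.fs, rng, n_channels=config.n_channels)
    sig *= config.pink_noise_amplitude
    if config.white_noise_amplitude > 0:
        sig += config.white_noise_amplitude * rng.standard_normal(sig.shape)

    # Line hum is a shared source: common phase per harmonic across channels.
    for h, amp in enumerate(config.hum_harmonic_amplitudes, start=1):
        f = h * config.hum_freq_hz
        if amp <= 0 or f >= config.fs / 2.0:
            continue
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sig += amp * np.sin(2.0 * np.pi * f * t + phase)

    if config.ramp_s > 0:
        ramp = np.clip((t - meta.onset_s) / config.ramp_s, 0.0, 1.0)
    else:
        ramp = (t >= meta.onset_s).astype(float)

    for band in BAND_NAMES:  # fixed order keeps the rng stream deterministic
        if not band_presence.get(band, False):
            continue
        spec = config.bands[band]
        if active_channels is not None and band in active_channels:
            chans = np.asarray(active_channels[band], dtype=int)
        else:
            chans = draw_active_channels(config, band, rng)
        for ch in chans:
            sig[ch] += _oscillation(spec, t, ramp, config.fs, rng)

    return Recording(
        signal=sig.astype(np.float32),
        fs=float(config.fs),
        channel_area=np.asarray(config.resolved_area_map(), dtype=object),
        meta=meta,
    )


def draw_presence(config: GeneratorConfig, divs: Sequence[int],
                  genotypes: Sequence[str], n_cultures_per_cell: int,
                  seed: int) -> pd.DataFrame:
    """Draw per-culture band presence from the occurrence models.

    Returns a long table (culture_id, genotype, div, band, present,
    probability) with one Bernoulli draw per culture x band; presence is a
    per-culture property shared by all its trials.
    """
    if n_cultures_per_cell < 1:
        raise ValueError("n_cultures_per_cell must be >= 1")
    divs = list(divs)
    genotypes = list(genotypes)
    if not divs or not genotypes:
        raise ValueError("divs and genotypes must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genotypes:
        for d in divs:
            for i in range(n_cultures_per_cell):
                cid = f"{g}-div{d:02d}-c{i:04d}"
                for band in BAND_NAMES:
                    p = config.occurrence[band].probability(g, d)
                    rows.append({
                        "culture_id": cid, "genotype": g, "div": int(d),
                        "band": band, "present": int(rng.random() < p),
                        "probability": p,
                    })
    return pd.DataFrame(rows)


@dataclass
class CultureData:
    """One simulated culture: its ground-truth presence and its trials."""

    culture_id: str
    genotype: str
    div: int
    presence: Dict[str, bool]
    active_channels: Dict[str, np.ndarray]
    recordings: List[Recording]


def generate_cohort(config: GeneratorConfig, n_cultures_per_cell: int,
                    divs: Sequence[int], genotypes: Sequence[str], seed: int,
                    n_trials: int = 6, signals: bool = True,
                    first_trial_index: int = 1) -> List[CultureData]:
    """Simulate a genotype x DIV cohort.

    Per cell, draws per-culture band presence from the logistic occurrence
    model, then (if ``signals``) emits ``n_trials`` trials per culture with
    trial 1 flagged as the discarded naive trial.  Active channel subsets are
    fixed per culture; noise and oscillation phases vary per trial.
    ``first_trial_index`` > 1 emits only retained (non-naive) trials, for
    screening runs that do not exercise the naive-trial exclusion.
    """
    presence_tab = draw_presence(config, divs, genotypes, n_cultures_per_cell, seed)
    ss = np.random.SeedSequence(seed)
    cultures = []
    grouped = presence_tab.groupby("culture_id", sort=False)
    children = ss.spawn(grouped.ngroups)
    for child, (cid, grp) in zip(children, grouped):
        genotype = grp["genotype"].iloc[0]
        div = int(grp["div"].iloc[0])
        presence = {r.band: bool(r.present) for r in grp.itertuples()}
        rng = np.random.default_rng(child)
        active = {b: draw_active_channels(config, b, rng)
                  for b in BAND_NAMES if presence.get(b)}
        recordings: List[Recording] = []
        if signals:
            for trial in range(first_trial_index, first_trial_index + n_trials):
                meta = TrialMeta(culture_id=cid, trial_index=trial,
                                 genotype=genotype, div=div,
                                 onset_s=config.onset_s,
                                 duration_s=config.duration_s)
                recordings.append(generate_recording(
                    config, meta, presence, rng=rng, active_channels=active))
        cultures.append(CultureData(culture_id=cid, genotype=genotype, div=div,
                                    presence=presence, active_channels=active,
                                    recordings=recordings))
    return cultures


def presence_table(cultures: Iterable[CultureData]) -> pd.DataFrame:
    """Ground-truth presence of a cohort as a long DataFrame."""
    rows = []
    for c in cultures:
        for band in BAND_NAMES:
            rows.append({"culture_id": c.culture_id, "genotype": c.genotype,
                         "div": c.div, "band": band,
                         "present": int(c.presence.get(band, False))})
    return pd.DataFrame(rows)
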
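"""Core containers for multichannel MEA oscillation analysis.

A *Recording* is one 60 s carbachol trial on a planar multielectrode array:
a channels x samples voltage matrix with a per-channel hippocampal-area label
(DG / CA3 / CA1) and trial metadata.  Spectral results move through a strict
pipeline of stages (``raw -> f_corrected -> notch_interpolated -> normalized``)
recorded explicitly on each :class:`ChannelSpectrum` so the order of the 1/f
correction, line-noise excision and sum-normalization steps is pinned down
rather than implicit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GENOTYPES = ("WT", "KO")
AREAS = ("DG", "CA3", "CA1")
OFF_TISSUE = "off_tissue"

#: Canonical oscillation bands, Hz.  Intervals are half-open [low, high):
#: 4 Hz belongs to theta, 10 Hz to beta, 30 Hz to gamma.
BAND_RANGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 10.0),
    "beta": (10.0, 30.0),
    "gamma": (30.0, 100.0),
}
BAND_NAMES = tuple(BAND_RANGES)

SPECTRUM_STAGES = ("raw", "f_corrected", "notch_interpolated", "normalized")


def classify_band(freq: float) -> Optional[str]:
    """Return the canonical band containing ``freq`` (half-open [low, high))."""
    for name, (lo, hi) in BAND_RANGES.items():
        if lo <= freq < hi:
            return name
    return None


@dataclass(frozen=True)
class TrialMeta:
    """Metadata of one carbachol trial.

    The stimulus is applied ``onset_s`` seconds into a ``duration_s`` second
    recording.  Trial 1 is the carbachol-naive control trial and is excluded
    from averaging.
    """

    culture_id: str
    trial_index: int
    genotype: str
    div: int
    onset_s: float = 30.0
    duration_s: float = 60.0

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if not (0 < self.onset_s < self.duration_s):
            raise ValueError(
                f"onset_s must lie strictly inside (0, duration_s): "
                f"onset={self.onset_s}, duration={self.duration_s}"
            )
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")

    @property
    def is_naive(self) -> bool:
        """True for the first (discarded) carbachol-naive trial."""
        return self.trial_index == 1


@dataclass
class Recording:
    """Multichannel voltage recording (channels x samples, microvolt scale)."""

    signal: np.ndarray
    fs: float
    channel_area: np.ndarray
    meta: TrialMeta

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        self.channel_area = np.asarray(self.channel_area, dtype=object)
        if self.channel_area.shape != (self.signal.shape[0],):
            raise ValueError(
                f"channel_area must have one label per channel "
                f"({self.signal.shape[0]}), got shape {self.channel_area.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channels_in(self, area: str) -> np.ndarray:
        """Indices of channels labelled with ``area``."""
        return np.flatnonzero(self.channel_area == area)


@dataclass
class Spectrogram:
    """Per-channel time-frequency power: channels x windows x frequencies."""

    power: np.ndarray
    freqs: np.ndarray
    window_starts: np.ndarray

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be channels x windows x frequencies")
        if self.power.shape[1:] != (self.window_starts.size, self.freqs.size):
            raise ValueError("power shape inconsistent with freqs/window_starts")


@dataclass
class ChannelSpectrum:
    """Per-channel power spectrum at one pipeline stage.

    ``inactive_channels`` marks channels with no signal power (all-zero
    spectrum); they are carried through but excluded from detection.
    """

    power: np.ndarray
    freqs: np.ndarray
    stage: str
    inactive_channels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be channels x frequencies")
        if self.power.shape[1] != self.freqs.size:
            raise ValueError("power columns must match frequency grid")
        if self.stage not in SPECTRUM_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {SPECTRUM_STAGES}")

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise ValueError(
                f"operation requires stage in {stages}, got {self.stage!r}; "
                f"the stage order {SPECTRUM_STAGES} is enforced"
            )

    def freq_index(self, freq: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs - freq)))
        if abs(self.freqs[idx] - freq) > 1e-9:
            raise ValueError(f"{freq} Hz is not on the frequency grid")
        return idx

    def subset(self, channels: Sequence[int]) -> "ChannelSpectrum":
        """Restrict to a channel subset (e.g. one hippocampal area)."""
        channels = np.asarray(channels, dtype=int)
        remap = {int(c): i for i, c in enumerate(channels)}
        inactive = frozenset(remap[c] for c in self.inactive_channels if c in remap)
        return ChannelSpectrum(
            power=self.power[channels],
            freqs=self.freqs,
            stage=self.stage,
            inactive_channels=inactive,
        )


@dataclass(frozen=True)
class Peak:
    """One spectral peak of one channel."""

    channel: int
    freq: float
    height: float
    prominence: float


@dataclass
class BandDetection:
    """Detection result for one canonical band over a channel set."""

    band: Optional[str]
    band_range: tuple
    search_range: tuple
    active_channels: tuple
    peaks: tuple
    mode_freq: Optional[float]
    present: bool
    peak_power_rel: Optional[float] = None
    channel_peak_power_rel: Optional[dict] = None
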
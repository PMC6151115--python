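"""Sliding-window DPSS multitaper spectral estimation and the spectrum
post-processing chain.

The short-time transform uses a 1 s window shifting by 100 ms over the whole
trial, with Slepian (DPSS) tapers.  The +/-2 Hz frequency smoothing is read
as the multitaper half-bandwidth W = 2 Hz, so the time-bandwidth product is
NW = window_s * W = 2 and K = 2NW - 1 = 3 tapers are averaged.  On a 1 s
window at 1 kHz the frequency grid is 1 Hz from 1 to 500 Hz.

Post-stimulus spectra then pass through a strictly ordered chain, recorded in
:attr:`ChannelSpectrum.stage`:

    raw -> f_corrected (multiply by frequency, flattens 1/f background)
        -> notch_interpolated (+/-3 Hz around each 50 Hz harmonic replaced by
           linear interpolation)
        -> normalized (each channel divided by its own sum).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as spfft
from scipy.signal import windows as spwin

from .core import ChannelSpectrum, Recording, Spectrogram, TrialMeta

_CHANNEL_CHUNK = 8  # channels transformed per FFT batch (memory bound)


@dataclass(frozen=True)
class SpectralConfig:
    window_s: float = 1.0
    step_s: float = 0.1
    fmin: float = 1.0
    fmax: float = 500.0
    smoothing_hw: float = 2.0  # multitaper half-bandwidth W, Hz
    line_freq: float = 50.0
    line_hw: float = 3.0
    ref_band: Tuple[float, float] = (200.0, 250.0)
    n_tapers: Optional[int] = None  # default 2*NW - 1

    def __post_init__(self):
        if self.smoothing_hw <= 0 or self.line_hw <= 0:
            raise ValueError("smoothing_hw and line_hw must be > 0")
        lo, hi = self.ref_band
        if not (self.fmin < lo < hi < self.fmax):
            raise ValueError("ref_band must lie strictly inside (fmin, fmax)")

    @property
    def time_bandwidth(self) -> float:
        return self.window_s * self.smoothing_hw

    @property
    def taper_count(self) -> int:
        if self.n_tapers is not None:
            return self.n_tapers
        return max(1, int(round(2 * self.time_bandwidth - 1)))


def dpss_tapers(n_win: int, cfg: SpectralConfig) -> np.ndarray:
    """Unit-energy Slepian tapers (K x n_win)."""
    return spwin.dpss(n_win, NW=cfg.time_bandwidth, Kmax=cfg.taper_count)


def multitaper_spectrogram(rec: Recording, cfg: SpectralConfig = SpectralConfig()
                           ) -> Spectrogram:
    """Multitaper short-time power over the whole trial.

    Window count follows floor((duration - window) / step) + 1; power in each
    window is the mean of the K tapered periodograms, one-sided, restricted to
    [fmin, fmax].
    """
    if cfg.fmax > rec.fs / 2.0 + 1e-9:
        raise ValueError(f"fmax {cfg.fmax} Hz exceeds Nyquist {rec.fs / 2} Hz")
    n_win = int(round(cfg.window_s * rec.fs))
    step = int(round(cfg.step_s * rec.fs))
    if rec.n_samples < n_win:
        raise ValueError(
            f"recording ({rec.duration_s:.3f} s) shorter than one {cfg.window_s} s window"
        )
    tapers = dpss_tapers(n_win, cfg)
    freqs_full = np.fft.rfftfreq(n_win, 1.0 / rec.fs)
    # [fmin, fmax] is a contiguous slice of the rfft grid
    i0 = int(np.searchsorted(freqs_full, cfg.fmin - 1e-9))
    i1 = int(np.searchsorted(freqs_full, cfg.fmax + 1e-9))
    freqs = freqs_full[i0:i1]

    # float32 input stays on the float32 FFT path (~2x faster; final power is
    # float64 and all later stages are full precision); float64 input keeps
    # full precision throughout.
    x = np.asarray(rec.signal)
    if x.dtype != np.float32:
        x = x.astype(float, copy=False)
    tap = tapers.astype(x.dtype)
    frames = sliding_window_view(x, n_win, axis=1)[:, ::step, :]  # C x W x n_win
    n_windows = frames.shape[1]
    power = np.empty((rec.n_channels, n_windows, freqs.size))
    for c0 in range(0, rec.n_channels, _CHANNEL_CHUNK):
        blk = frames[c0:c0 + _CHANNEL_CHUNK]
        acc = None
        for k in range(tap.shape[0]):
            spec = spfft.rfft(blk * tap[k], axis=-1)
            p = spec.real ** 2 + spec.imag ** 2
            acc = p if acc is None else acc + p
        # one-sided PSD convention: 2/fs times the mean tapered periodogram
        power[c0:c0 + _CHANNEL_CHUNK] = acc[..., i0:i1] * (2.0 / (tap.shape[0] * rec.fs))

    window_starts = np.arange(n_windows) * step / rec.fs
    return Spectrogram(power=power, freqs=freqs, window_starts=window_starts)


def post_stim_spectrum(spec: Spectrogram, onset_s: float) -> ChannelSpectrum:
    """Mean spectrum over all windows starting at or after the stimulus onset."""
    sel = spec.window_starts >= onset_s - 1e-9
    if not np.any(sel):
        raise ValueError(f"no analysis window starts after onset {onset_s} s")
    return ChannelSpectrum(power=spec.power[:, sel, :].mean(axis=1),
                           freqs=spec.freqs, stage="raw")


def pre_stim_spectrum(spec: Spectrogram, onset_s: float,
                      window_s: float = 1.0) -> ChannelSpectrum:
    """Mean spectrum over windows entirely before the onset (baseline)."""
    sel = spec.window_starts + window_s <= onset_s + 1e-9
    if not np.any(sel):
        raise ValueError(f"no analysis window ends before onset {onset_s} s")
    return ChannelSpectrum(power=spec.power[:, sel, :].mean(axis=1),
                           freqs=spec.freqs, stage="raw")


def correct_one_over_f(cs: ChannelSpectrum) -> ChannelSpectrum:
    """Multiply every power value by its frequency (flattens 1/f background)."""
    cs.require_stage("raw")
    return ChannelSpectrum(power=cs.power * cs.freqs[np.newaxis, :],
                           freqs=cs.freqs, stage="f_corrected",
                           inactive_channels=cs.inactive_channels)


def line_harmonics(cfg: SpectralConfig) -> List[float]:
    """Harmonics of the line frequency inside [fmin, fmax]."""
    out = []
    h = 1
    while h * cfg.line_freq <= cfg.fmax + 1e-9:
        if h * cfg.line_freq >= cfg.fmin:
            out.append(h * cfg.line_freq)
        h += 1
    return out


def excise_line_noise(cs: ChannelSpectrum, cfg: SpectralConfig = SpectralConfig()
                      ) -> ChannelSpectrum:
    """Cut +/-line_hw around every line harmonic and bridge the gap linearly.

    Power on the open interval (h*f0 - hw, h*f0 + hw) is replaced by the line
    through the values at the interval's boundary grid points.  Where a
    boundary falls outside the grid, the interval is clipped and the available
    boundary value is held flat.
    """
    cs.require_stage("f_corrected")
    power = cs.power.copy()
    f = cs.freqs
    for f0 in line_harmonics(cfg):
        lo, hi = f0 - cfg.line_hw, f0 + cfg.line_hw
        inner = np.flatnonzero((f > lo + 1e-9) & (f < hi - 1e-9))
        if inner.size == 0:
            continue
        ilo = np.flatnonzero(np.isclose(f, lo, atol=1e-9))
        ihi = np.flatnonzero(np.isclose(f, hi, atol=1e-9))
        has_lo, has_hi = ilo.size > 0, ihi.size > 0
        if has_lo and has_hi:
            vlo = power[:, ilo[0]]
            vhi = power[:, ihi[0]]
            w = (f[inner] - lo) / (hi - lo)
            power[:, inner] = vlo[:, None] * (1 - w)[None, :] + vhi[:, None] * w[None, :]
        elif has_lo:
            power[:, inner] = power[:, ilo[0]][:, None]
        elif has_hi:
            power[:, inner] = power[:, ihi[0]][:, None]
        # neither boundary on the grid: harmonic effectively outside range
    return ChannelSpectrum(power=power, freqs=f, stage="notch_interpolated",
                           inactive_channels=cs.inactive_channels)


def normalize_spectrum(cs: ChannelSpectrum) -> ChannelSpectrum:
    """Divide each channel by its own spectrum sum (unit-sum spectra).

    All-zero channels are flagged inactive (excluded from detection) rather
    than raising.  Re-normalizing an already normalized spectrum is a no-op.
    """
    cs.require_stage("notch_interpolated", "normalized")
    sums = cs.power.sum(axis=1)
    inactive = set(cs.inactive_channels) | {int(i) for i in np.flatnonzero(sums == 0)}
    safe = np.where(sums == 0, 1.0, sums)
    return ChannelSpectrum(power=cs.power / safe[:, None], freqs=cs.freqs,
                           stage="normalized",
                           inactive_channels=frozenset(inactive))


def average_trials(spectra: Sequence[ChannelSpectrum],
                   metas: Sequence[TrialMeta]) -> ChannelSpectrum:
    """Element-wise mean over a culture's non-naive trials.

    Trial 1 (the carbachol-naive control) is dropped; the expected input is
    six trials of one culture, giving a five-trial average.
    """
    if len(spectra) != len(metas):
        raise ValueError("spectra and metas must align")
    if len(spectra) < 2:
        raise ValueError("averaging needs at least two trials")
    stage = spectra[0].stage
    freqs = spectra[0].freqs
    culture = metas[0].culture_id
    for cs, m in zip(spectra, metas):
        if cs.stage != stage:
            raise ValueError("all trial spectra must be at the same stage")
        if not np.array_equal(cs.freqs, freqs):
            raise ValueError("all trial spectra must share one frequency grid")
        if m.culture_id != culture:
            raise ValueError("average_trials operates within a single culture")
    keep = [cs for cs, m in zip(spectra, metas) if not m.is_naive]
    if not keep:
        raise ValueError("all trials are flagged naive; nothing to average")
    power = np.mean([cs.power for cs in keep], axis=0)
    inactive = frozenset.intersection(*[frozenset(cs.inactive_channels) for cs in keep])
    return ChannelSpectrum(power=power, freqs=freqs, stage=stage,
                           inactive_channels=inactive)


def spectrum_to_frame(cs: ChannelSpectrum, culture_id: str,
                      channel_area: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Long-format export: culture_id, channel, area, freq_hz, power, stage."""
    n_ch, n_f = cs.power.shape
    areas = (np.asarray(channel_area, dtype=object) if channel_area is not None
             else np.asarray(["NA"] * n_ch, dtype=object))
    return pd.DataFrame({
        "culture_id": np.repeat(culture_id, n_ch * n_f),
        "channel": np.repeat(np.arange(n_ch), n_f),
        "area": np.repeat(areas, n_f),
        "freq_hz": np.tile(cs.freqs, n_ch),
        "power": cs.power.ravel(),
        "stage": cs.stage,
    })
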
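"""Prominence-based oscillation detection and band categorization.

A channel is *active* in a band when its best spectral peak inside the band
has prominence >= 0.001 normalized units — the threshold below which a peak
stops being a small-but-distinguishable bump in the normalized spectrum.
Prominence of a local maximum: extend a horizontal line left and right until
it crosses the signal (a strictly higher sample) or reaches the end, take the
minimum of each interval, and subtract the higher of the two minima from the
peak height.

Peaks are located on the full normalized spectrum and then attributed to the
half-open canonical ranges delta [1,4), theta [4,10), beta [10,30), gamma
[30,100) Hz; the band label of a detection follows the mode of the active
channels' peak frequencies.  Slicing the spectrum per band first would make
narrow bands (delta spans 3 grid points at 1 Hz resolution) undetectable at
their edges, so full-spectrum prominence is used throughout.
"""
from __future__ import annotations

from collections import Counter
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import (BAND_NAMES, BAND_RANGES, BandDetection, ChannelSpectrum,
                   Peak, classify_band)

PROMINENCE_THRESHOLD = 0.001  # normalized units


def peak_prominence(values: Sequence[float]) -> List[Tuple[int, float, float]]:
    """All local maxima of a vector with their heights and prominences.

    Flat-topped (plateau) maxima are reported once, at the plateau's center
    grid point.  Returns (index, height, prominence) tuples in index order.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("peak_prominence needs a 1-D vector of length >= 3")
    idx, props = sps.find_peaks(v, prominence=0.0)
    return [(int(i), float(v[i]), float(p)) for i, p in zip(idx, props["prominences"])]


def _best_peak_in_range(freqs: np.ndarray, peaks: List[Tuple[int, float, float]],
                        lo: float, hi: float) -> Optional[Tuple[int, float, float]]:
    """Highest-prominence peak with frequency in [lo, hi); ties -> lowest freq."""
    best = None
    for i, h, p in peaks:
        f = freqs[i]
        if lo <= f < hi:
            if best is None or p > best[2] or (p == best[2] and f < freqs[best[0]]):
                best = (i, h, p)
    return best


def mode_frequency(freqs: Sequence[float]) -> float:
    """Mode of peak frequencies; equally common values break to the lowest."""
    counts = Counter(float(f) for f in freqs)
    best_count = max(counts.values())
    return min(f for f, c in counts.items() if c == best_count)


def detect_band(cs: ChannelSpectrum, search_range: Tuple[float, float],
                threshold: float = PROMINENCE_THRESHOLD) -> BandDetection:
    """Detect an oscillation inside ``search_range`` on a normalized spectrum.

    Per channel the highest-prominence peak inside the (half-open) range is
    taken; channels whose best peak reaches the prominence threshold are
    active.  The detection's mode frequency is the mode of active channels'
    peak frequencies and the band label is the canonical range containing it.
    With no active channel the band is absent and mode_freq is None.
    """
    cs.require_stage("normalized")
    lo, hi = float(search_range[0]), float(search_range[1])
    if not np.any((cs.freqs >= lo) & (cs.freqs < hi)):
        raise ValueError(f"search range [{lo}, {hi}) contains no grid frequency")
    active: List[int] = []
    peaks: List[Peak] = []
    for ch in range(cs.n_channels):
        if ch in cs.inactive_channels:
            continue
        cand = _best_peak_in_range(cs.freqs, peak_prominence(cs.power[ch]), lo, hi)
        if cand is not None and cand[2] >= threshold:
            active.append(ch)
            peaks.append(Peak(channel=ch, freq=float(cs.freqs[cand[0]]),
                              height=cand[1], prominence=cand[2]))
    present = len(active) > 0
    mode_f = mode_frequency([p.freq for p in peaks]) if present else None
    return BandDetection(
        band=classify_band(mode_f) if present else None,
        band_range=BAND_RANGES.get(classify_band(mode_f), (lo, hi)) if present else (lo, hi),
        search_range=(lo, hi),
        active_channels=tuple(active),
        peaks=tuple(peaks),
        mode_freq=mode_f,
        present=present,
    )


def scan_bands(cs: ChannelSpectrum, threshold: float = PROMINENCE_THRESHOLD
               ) -> List[BandDetection]:
    """Run detection over the four canonical ranges, independently per band."""
    return [detect_band(cs, BAND_RANGES[b], threshold) for b in BAND_NAMES]


def relative_peak_power(cs: ChannelSpectrum, det: BandDetection,
                        ref_band: Tuple[float, float] = (200.0, 250.0)) -> float:
    """Peak power relative to the mean power in the reference band.

    Evaluated on the frequency-corrected (optionally line-excised) spectrum:
    per active channel, power at its detected peak frequency divided by the
    mean power over the inclusive reference band; the band-level summary is
    the mean over active channels, also stored per channel on ``det``.
    The quantity is invariant to any overall rescaling of the spectrum.
    """
    if not det.present:
        raise ValueError("relative_peak_power requires a present detection")
    cs.require_stage("f_corrected", "notch_interpolated")
    lo, hi = ref_band
    ref_mask = (cs.freqs >= lo - 1e-9) & (cs.freqs <= hi + 1e-9)
    if not np.any(ref_mask):
        raise ValueError(f"reference band [{lo}, {hi}] is not on the grid")
    per_channel = {}
    for p in det.peaks:
        ref = float(cs.power[p.channel, ref_mask].mean())
        if ref == 0:
            raise ZeroDivisionError(
                f"zero reference power in [{lo}, {hi}] Hz on channel {p.channel}"
            )
        per_channel[p.channel] = float(cs.power[p.channel, cs.freq_index(p.freq)] / ref)
    summary = float(np.mean(list(per_channel.values())))
    det.peak_power_rel = summary
    det.channel_peak_power_rel = per_channel
    return summary
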
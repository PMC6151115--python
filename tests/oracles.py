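"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive quantities from first principles (definition
walks, direct periodograms) and never call the code paths they check.
"""
import numpy as np


def brute_force_peak_prominences(values):
    """Peak prominence straight from the definition.

    A local maximum (plateaus count once, at their center point, and must
    fall strictly on both sides) has a horizontal line extended left and
    right until it crosses a strictly higher sample or the end of the
    signal; the minimum of each interval is taken and the prominence is the
    height above the higher of the two minima.  Returns (index, height,
    prominence) tuples in index order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    out = []
    i = 1
    while i < n - 1:
        if v[i] <= v[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and v[j + 1] < v[i]:
            mid = (i + j) // 2
            h = v[i]
            left = v[:i][::-1]
            higher = np.flatnonzero(left > h)
            stop = higher[0] if higher.size else left.size
            left_min = left[:stop].min()
            right = v[j + 1:]
            higher = np.flatnonzero(right > h)
            stop = higher[0] if higher.size else right.size
            right_min = right[:stop].min()
            out.append((int(mid), float(h), float(h - max(left_min, right_min))))
        i = j + 1
    return out


def bandpower(x, fs, f_lo, f_hi):
    """Direct-periodogram power of a signal segment in [f_lo, f_hi]."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    return float(spec[sel].sum()) / x.size
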
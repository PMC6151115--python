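"""Multitaper spectrogram and the spectrum post-processing chain."""
import numpy as np
import pytest
from scipy import signal as sps

from cholosc.core import ChannelSpectrum, Recording, TrialMeta
from cholosc.spectral import (SpectralConfig, average_trials,
                              correct_one_over_f, dpss_tapers,
                              excise_line_noise, line_harmonics,
                              multitaper_spectrogram, normalize_spectrum,
                              post_stim_spectrum)

META = TrialMeta("sp", 2, "WT", 13)
CFG = SpectralConfig()


def _rec(signal, fs=1000.0, onset=30.0):
    sig = np.atleast_2d(signal)
    meta = TrialMeta("sp", 2, "WT", 13, onset_s=onset,
                     duration_s=sig.shape[1] / fs)
    return Recording(sig, fs, np.array(["DG"] * sig.shape[0]), meta)


def _spectrum(power, stage="raw"):
    power = np.atleast_2d(np.asarray(power, float))
    return ChannelSpectrum(power=power,
                           freqs=np.arange(1.0, power.shape[1] + 1.0),
                           stage=stage)


# ---------------------------------------------------------------- spectrogram

def test_window_grid_of_standard_trial(rng):
    """60 s trial, 1 s window, 100 ms shift -> 591 windows on a 1 Hz grid
    from 1 to 500 Hz; 291 of them start at/after the 30 s onset."""
    rec = _rec(rng.standard_normal(60000))
    sg = multitaper_spectrogram(rec, CFG)
    assert sg.power.shape == (1, 591, 500)
    assert np.array_equal(sg.freqs, np.arange(1.0, 501.0))
    assert np.all(sg.power >= 0)
    post = post_stim_spectrum(sg, 30.0)
    n_post = np.sum(sg.window_starts >= 30.0 - 1e-9)
    assert n_post == 291


def test_dpss_taper_count_and_orthonormality():
    """NW = 1 s x 2 Hz = 2 gives K = 3 mutually orthonormal Slepians."""
    tapers = dpss_tapers(1000, CFG)
    assert tapers.shape[0] == 3
    gram = tapers @ tapers.T
    assert np.allclose(np.diag(gram), 1.0, atol=1e-8)
    assert np.max(np.abs(gram - np.diag(np.diag(gram)))) < 1e-8


def test_sinusoid_peak_matches_periodogram_oracle(rng):
    """A 40 Hz sinusoid in white noise (power SNR 10) peaks at 40 +/- 1 Hz,
    in agreement with a plain periodogram."""
    t = np.arange(60000) / 1000.0
    noise = rng.standard_normal(t.size) * np.sqrt(0.5 / 10)
    sig = np.sin(2 * np.pi * 40 * t) + noise
    sg = multitaper_spectrogram(_rec(sig), CFG)
    cs = post_stim_spectrum(sg, 30.0)
    assert abs(cs.freqs[np.argmax(cs.power[0])] - 40.0) <= 1.0
    f_p, p = sps.periodogram(sig, fs=1000.0)
    assert abs(f_p[np.argmax(p)] - 40.0) <= 1.0


def test_recording_shorter_than_window_rejected(rng):
    with pytest.raises(ValueError, match="window"):
        multitaper_spectrogram(_rec(rng.standard_normal(500), onset=0.1), CFG)


def test_white_noise_spectrum_is_flat(rng):
    """Channel-mean multitaper spectrum of white noise varies by less than
    a factor 2 over 5-450 Hz on a 60 s average."""
    rec = _rec(rng.standard_normal((4, 60000)))
    sg = multitaper_spectrogram(rec, CFG)
    mean = sg.power.mean(axis=(0, 1))
    sel = (sg.freqs >= 5) & (sg.freqs <= 450)
    assert mean[sel].max() / mean[sel].min() < 2.0


def test_single_taper_agrees_with_hann_periodogram(rng):
    """K=1 multitaper and a Hann-windowed periodogram concentrate the same
    power around a sinusoid peak (35-45 Hz band integral within 5%)."""
    t = np.arange(60000) / 1000.0
    sig = np.sin(2 * np.pi * 40 * t) + 0.3 * rng.standard_normal(t.size)
    cfg1 = SpectralConfig(n_tapers=1)
    sg = multitaper_spectrogram(_rec(sig), cfg1)
    mt = post_stim_spectrum(sg, 30.0)
    starts = (np.arange(591) * 100)[300:]
    acc = 0.0
    for s0 in starts:
        f_p, p = sps.periodogram(sig[s0:s0 + 1000], fs=1000.0, window="hann")
        acc = acc + p
    hann = acc / len(starts)
    m_mt = (mt.freqs >= 35) & (mt.freqs <= 45)
    m_h = (f_p >= 35) & (f_p <= 45)
    assert mt.power[0, m_mt].sum() == pytest.approx(hann[m_h].sum(), rel=0.05)


# ------------------------------------------------------------ post-stimulus

def test_post_stim_mean_of_constant_spectrogram(rng):
    rec = _rec(rng.standard_normal(60000))
    sg = multitaper_spectrogram(rec, CFG)
    sg.power[:] = sg.power[:, :1, :]  # constant in time
    cs = post_stim_spectrum(sg, 30.0)
    assert np.allclose(cs.power, sg.power[:, 0, :])
    assert cs.stage == "raw"


def test_post_stim_requires_windows_after_onset(rng):
    sg = multitaper_spectrogram(_rec(rng.standard_normal(60000)), CFG)
    with pytest.raises(ValueError, match="onset"):
        post_stim_spectrum(sg, 60.0)


# ------------------------------------------------------- 1/f and line noise

def test_one_over_f_correction_identity():
    freqs = np.arange(1.0, 501.0)
    cs = ChannelSpectrum(power=(1.0 / freqs)[None, :], freqs=freqs, stage="raw")
    out = correct_one_over_f(cs)
    assert np.allclose(out.power, 1.0)
    assert out.stage == "f_corrected"
    zeros = correct_one_over_f(_spectrum(np.zeros(500)))
    assert np.all(zeros.power == 0)


def test_pipeline_stage_order_enforced():
    cs = _spectrum(np.ones(500), stage="raw")
    with pytest.raises(ValueError, match="stage"):
        excise_line_noise(cs, CFG)
    with pytest.raises(ValueError, match="stage"):
        normalize_spectrum(cs)
    with pytest.raises(ValueError, match="stage"):
        correct_one_over_f(_spectrum(np.ones(500), stage="normalized"))


def test_excision_flat_and_sloped_interpolation():
    power = np.ones(500)
    power[49] = 1e6  # huge hum spike at 50 Hz
    out = excise_line_noise(_spectrum(power, "f_corrected"), CFG)
    assert np.allclose(out.power[0, 47:52], 1.0)  # 48..52 Hz all flat
    assert out.stage == "notch_interpolated"

    power = np.ones(500)
    power[46] = 0.0   # 47 Hz
    power[52] = 6.0   # 53 Hz
    power[49] = 1e6
    out = excise_line_noise(_spectrum(power, "f_corrected"), CFG)
    assert out.power[0, 49] == pytest.approx(3.0)  # midpoint of the line


def test_excision_covers_all_ten_harmonics():
    """Ten 50 Hz harmonics lie in 1-500 Hz; each excised interval becomes an
    exact linear segment between its boundary grid points."""
    cfg = SpectralConfig()
    assert line_harmonics(cfg) == [50.0 * h for h in range(1, 11)]
    rng = np.random.default_rng(0)
    power = 1.0 + 0.1 * rng.random(500)
    spiky = power.copy()
    for h in range(1, 11):
        lo = max(50 * h - 2, 1)
        for f in range(lo, min(50 * h + 3, 501)):
            spiky[f - 1] += 100.0
    out = excise_line_noise(_spectrum(spiky, "f_corrected"), cfg)
    freqs = np.arange(1.0, 501.0)
    for h in range(1, 11):
        f0 = 50.0 * h
        inner = (freqs > f0 - 3) & (freqs < f0 + 3)
        vals = out.power[0, inner]
        if f0 + 3 <= 500:
            v_lo = out.power[0, int(f0 - 3) - 1]
            v_hi = out.power[0, int(f0 + 3) - 1]
            expected = v_lo + (v_hi - v_lo) * (freqs[inner] - (f0 - 3)) / 6.0
        else:  # clipped top interval held flat at the left boundary
            expected = np.full(vals.size, out.power[0, int(f0 - 3) - 1])
        assert np.allclose(vals, expected, rtol=0, atol=1e-12)
        assert np.all(vals < 50.0)  # spike removed


# ------------------------------------------------------------- normalization

def test_normalization_values_and_idempotence():
    cs = _spectrum([[3.0, 1.0]], stage="notch_interpolated")
    out = normalize_spectrum(cs)
    assert np.allclose(out.power, [[0.75, 0.25]])
    again = normalize_spectrum(out)
    assert np.allclose(again.power, out.power)
    assert out.stage == "normalized"


def test_normalization_unit_sums_and_inactive_flagging(rng):
    power = rng.random((5, 500))
    power[2] = 0.0  # a silent channel
    out = normalize_spectrum(_spectrum(power, "notch_interpolated"))
    sums = out.power.sum(axis=1)
    assert np.all(np.abs(sums[[0, 1, 3, 4]] - 1.0) < 1e-9)
    assert 2 in out.inactive_channels
    assert np.all(out.power[2] == 0)


# ----------------------------------------------------------- trial averaging

def _trial_spectra(values_per_trial):
    metas, spectra = [], []
    for i, val in enumerate(values_per_trial, start=1):
        metas.append(TrialMeta("cult", i, "WT", 13))
        spectra.append(_spectrum(np.full((2, 10), float(val)), "normalized"))
    return spectra, metas


def test_average_drops_naive_first_trial():
    """Six trials, trial 1 wildly different: the average is over trials 2-6."""
    spectra, metas = _trial_spectra([100.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    out = average_trials(spectra, metas)
    assert np.allclose(out.power, 1.0)


def test_average_of_identical_trials_is_identity():
    spectra, metas = _trial_spectra([2.0] * 6)
    out = average_trials(spectra, metas)
    assert np.allclose(out.power, 2.0)


def test_average_rejects_all_naive_or_single_trial():
    spectra, metas = _trial_spectra([1.0])
    with pytest.raises(ValueError):
        average_trials(spectra, metas)
    s2, m2 = _trial_spectra([1.0, 2.0])
    m2 = [m2[0], m2[0]]  # both flagged as trial 1
    with pytest.raises(ValueError, match="naive"):
        average_trials(s2, m2)
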
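"""Windowing arithmetic, band-bin mapping, band power vs a direct-DFT
oracle, feature extraction layout, and standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegemotion.io import Recording
from eegemotion.spectral import (
    BandSpec, DEFAULT_BANDS, band_bins, band_power, extract_features,
    plan_windows, standardize,
)


def brute_force_starts(L, W, S):
    """Independent enumeration of the strict window-inclusion rule."""
    return [s for s in range(0, L, S) if s % S == 0 and s + W < L]


def direct_dft_band_power(x, fs, bands):
    """O(N^2) DFT of the definition, then one-sided band magnitude sums."""
    n = len(x)
    k = np.arange(n // 2 + 1)
    ang = -2j * np.pi * np.outer(k, np.arange(n)) / n
    mags = np.abs(np.exp(ang) @ x)
    out = []
    for band in bands:
        freqs = k * fs / n
        sel = (freqs >= band.low) & (freqs < band.high)
        out.append(mags[sel].sum())
    return np.array(out)


# ---------------------------------------------------------------- windowing

@pytest.mark.parametrize("L,W,S,expected", [
    (8064, 256, 16, 488),      # 19,520 rows / 40 trials
    (8064, 1024, 16, 440),
    (8064, 4, 16, 504),
    (256, 256, 16, 0),         # start + W < L admits nothing at L == W
])
def test_plan_windows_counts(L, W, S, expected):
    plan = plan_windows(L, W, S)
    assert plan.n_windows == expected
    assert list(plan.starts) == brute_force_starts(L, W, S)


@given(L=st.integers(1, 10_000), W=st.sampled_from([4, 16, 100, 256, 1024]),
       S=st.integers(1, 64))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_plan_windows_matches_brute_force(L, W, S):
    plan = plan_windows(L, W, S)
    assert list(plan.starts) == brute_force_starts(L, W, S)
    assert all(s + W < L for s in plan.starts)


def test_invalid_window_plan_rejected():
    with pytest.raises(ValueError):
        plan_windows(100, 0, 16)
    with pytest.raises(ValueError):
        plan_windows(100, 16, 0)


# ---------------------------------------------------------------- band bins

@pytest.mark.parametrize("W,band,expected", [
    (256, BandSpec("theta", 4, 8), list(range(8, 16))),       # 0.5 Hz bins
    (4, BandSpec("theta", 4, 8), []),                         # 32 Hz bins
    (128, BandSpec("gamma", 25, 45), list(range(25, 45))),    # 1 Hz bins
])
def test_band_bins_enumeration(W, band, expected):
    assert list(band_bins(W, 128.0, band)) == expected


def test_band_bins_disjoint_across_default_bank():
    all_bins = np.concatenate(
        [band_bins(256, 128.0, b) for b in DEFAULT_BANDS])
    assert len(all_bins) == len(set(all_bins))      # half-open edges
    assert 0 not in all_bins                        # DC excluded


# --------------------------------------------------------------- band power

def test_zero_window_gives_zero_powers():
    assert np.all(band_power(np.zeros(256), 128.0) == 0.0)


def test_on_bin_sinusoid_concentrates_in_alpha():
    t = np.arange(256) / 128.0
    x = np.sin(2 * np.pi * 10.0 * t)                # exactly bin 20
    p = dict(zip([b.name for b in DEFAULT_BANDS], band_power(x, 128.0)))
    for name, val in p.items():
        if name != "alpha":
            assert p["alpha"] > 100 * val


def test_band_power_matches_direct_dft_oracle(rng):
    for _ in range(50):
        w = int(rng.choice([64, 128, 256]))
        x = rng.standard_normal(w)
        fast = band_power(x, 128.0)
        slow = direct_dft_band_power(x, 128.0, DEFAULT_BANDS)
        np.testing.assert_allclose(fast, slow, rtol=1e-9)


def test_band_power_rejects_non_1d():
    with pytest.raises(ValueError):
        band_power(np.zeros((2, 128)), 128.0)


# --------------------------------------------------------------- extraction

def _single_trial_recording(seed=0, n_samples=8064):
    rng = np.random.default_rng(seed)
    return Recording(data=rng.standard_normal((1, 40, n_samples)),
                     ratings=np.array([[2.0, 7.0, 4.0, 6.0]]))


def test_single_trial_extraction_shape_and_provenance():
    rec = _single_trial_recording()
    m = extract_features(rec)
    assert m.values.shape == (488, 70)
    assert m.feature_names[:5] == [
        "Fp1_theta", "Fp1_alpha", "Fp1_low_beta", "Fp1_high_beta", "Fp1_gamma"]
    assert np.all(m.trial_index == 0)
    assert list(m.start_offset[:3]) == [0, 16, 32]
    np.testing.assert_array_equal(m.ratings, np.tile([2.0, 7.0, 4.0, 6.0], (488, 1)))


def test_extraction_rows_match_per_window_band_power():
    rec = _single_trial_recording(n_samples=600)
    m = extract_features(rec, window_size=256, step=64)
    # row 2, channel F3 (3rd selected electrode) against direct computation
    start = m.start_offset[2]
    window = rec.data[0, 2, start:start + 256]      # F3 is Geneva index 2
    np.testing.assert_allclose(
        m.values[2, 10:15], band_power(window, 128.0), rtol=1e-12)


def test_permuting_bands_permutes_columns():
    rec = _single_trial_recording(n_samples=600)
    fwd = extract_features(rec, window_size=128, step=64, bands=DEFAULT_BANDS)
    rev = extract_features(rec, window_size=128, step=64,
                           bands=tuple(reversed(DEFAULT_BANDS)))
    n_b = len(DEFAULT_BANDS)
    for c in range(14):
        np.testing.assert_array_equal(
            rev.values[:, c * n_b:(c + 1) * n_b],
            fwd.values[:, c * n_b:(c + 1) * n_b][:, ::-1])


# ----------------------------------------------------------- standardization

def test_standardize_zscores_columns(rng):
    rec = _single_trial_recording(n_samples=600)
    m = extract_features(rec, window_size=128, step=16)
    z, scaler = standardize(m)
    assert z.standardized
    np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.values.std(axis=0), 1.0, atol=1e-9)
    # stored statistics invert the transform
    back = z.values * scaler.scale_ + scaler.mean_
    np.testing.assert_allclose(back, m.values, rtol=1e-9)


def test_constant_column_warns_and_keeps_scale_one(caplog):
    from dataclasses import replace

    rec = _single_trial_recording(n_samples=600)
    m = extract_features(rec, window_size=128, step=16)
    values = m.values.copy()
    values[:, 3] = 42.0
    m = replace(m, values=values)
    with caplog.at_level("WARNING", logger="eegemotion.spectral"):
        z, _ = standardize(m)
    assert "zero-variance" in caplog.text
    np.testing.assert_allclose(z.values[:, 3], 0.0, atol=1e-12)
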
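"""Wavelet-coherence core: period band, CWT, smoothing, COI, ROI pairs."""

import numpy as np
import pytest

from dyadsync import wtc as W
from dyadsync.simulate import SimulationConfig, bandlimited_noise, generate_dyad_timeseries

FS = 7.81


# ---------------------------------------------------------------------------
# adaptive period range
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "duration, expected",
    [(300.0, (8.0, 75.0)), (32.0, (8.0, 8.0)), (600.0, (8.0, 150.0))],
)
def test_adaptive_period_range(duration, expected):
    assert W.adaptive_period_range(duration) == expected


def test_adaptive_period_range_too_short():
    with pytest.raises(W.SegmentTooShortError):
        W.adaptive_period_range(20.0)


# ---------------------------------------------------------------------------
# Morlet CWT
# ---------------------------------------------------------------------------

def test_cwt_zero_signal():
    periods = W.period_grid(8, 32)
    c = W.morlet_cwt(np.zeros(256), FS, periods)
    assert np.allclose(c.coeffs, 0.0)


def test_cwt_rejects_nan():
    with pytest.raises(ValueError):
        W.morlet_cwt(np.array([0.0, np.nan, 1.0]), FS, np.array([8.0]))


def test_cwt_linearity(rng):
    periods = W.period_grid(8, 32)
    x = rng.standard_normal(300)
    c1 = W.morlet_cwt(x, FS, periods)
    c2 = W.morlet_cwt(2.0 * x, FS, periods)
    assert np.allclose(c2.coeffs, 2.0 * c1.coeffs, atol=1e-12)


def test_cwt_sinusoid_peaks_at_its_period():
    target = 30.0
    n = int(600 * FS)
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * t / target)
    periods = W.period_grid(8, 75)
    c = W.morlet_cwt(x, FS, periods)
    mid = n // 2
    i = np.argmax(np.abs(c.coeffs[:, mid]))
    # within one scale step of the true period
    step = periods[1] / periods[0]
    assert periods[i] / step <= target <= periods[i] * step


@pytest.mark.parametrize("target", [10.0, 30.0, 60.0])
def test_shared_sinusoid_coherence_peaks_at_period(rng, target):
    """Band-restricted coherence peaks within one scale step of the shared
    sinusoid's period when both partners carry it plus independent noise."""
    n = int(600 * FS)
    t = np.arange(n) / FS
    s = np.sin(2 * np.pi * t / target)
    x = s + 0.5 * rng.standard_normal(n)
    y = s + 0.5 * rng.standard_normal(n)
    periods = W.period_grid(8, 75)
    wm = W.compute_wtc(W.morlet_cwt(x, FS, periods), W.morlet_cwt(y, FS, periods))
    prof = np.where(wm.coi_mask, wm.coherence, np.nan)
    mean_per_period = np.nanmean(prof, axis=1)
    i = np.nanargmax(mean_per_period)
    step = periods[1] / periods[0]
    assert periods[i] / step**2 <= target <= periods[i] * step**2


# ---------------------------------------------------------------------------
# coherence properties
# ---------------------------------------------------------------------------

def _pair(rng, n=512):
    periods = W.period_grid(8, 40)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    return W.morlet_cwt(x, FS, periods), W.morlet_cwt(y, FS, periods)


def test_self_coherence_is_one(rng):
    cx, _ = _pair(rng)
    wm = W.compute_wtc(cx, cx)
    assert np.abs(wm.coherence - 1.0).max() < 1e-6


def test_coherence_bounded(rng):
    cx, cy = _pair(rng)
    wm = W.compute_wtc(cx, cy)
    assert wm.coherence.min() >= 0.0 and wm.coherence.max() <= 1.0


def test_coherence_symmetry(rng):
    cx, cy = _pair(rng)
    a = W.compute_wtc(cx, cy).coherence
    b = W.compute_wtc(cy, cx).coherence
    assert np.abs(a - b).max() < 1e-10


def test_coherence_scaling_invariance(rng):
    periods = W.period_grid(8, 40)
    x = rng.standard_normal(512)
    y = rng.standard_normal(512)
    a = W.compute_wtc(W.morlet_cwt(x, FS, periods), W.morlet_cwt(y, FS, periods)).coherence
    b = W.compute_wtc(W.morlet_cwt(3.7 * x, FS, periods), W.morlet_cwt(0.2 * y, FS, periods)).coherence
    assert np.abs(a - b).max() < 1e-8


def test_time_shifted_copy_stays_coherent(rng):
    """A 2 s shift is small against 8-75 s periods: coherence stays near 1."""
    n = int(300 * FS)
    shift = int(round(2 * FS))
    base = bandlimited_noise(rng, n + shift, FS, (8, 75))
    periods = W.period_grid(8, 75)
    cx = W.morlet_cwt(base[:n], FS, periods)
    cy = W.morlet_cwt(base[shift:shift + n], FS, periods)
    v, _ = W.mask_and_average(W.compute_wtc(cx, cy))
    assert v > 0.9


def test_independent_noise_null_level(rng):
    """Smoothing-induced bias level for independent white noise (n = 2340
    samples = 5 min at 7.81 Hz, band 8-75 s): positive but well below 0.75.

    The empirical null mean of this configuration is ~0.43; frozen band for
    regression."""
    vals = []
    periods = W.period_grid(8, 75)
    for _ in range(20):
        cx = W.morlet_cwt(rng.standard_normal(2340), FS, periods)
        cy = W.morlet_cwt(rng.standard_normal(2340), FS, periods)
        vals.append(W.mask_and_average(W.compute_wtc(cx, cy))[0])
    m = np.mean(vals)
    assert 0.0 < m < 0.75
    assert 0.35 < m < 0.52  # regression band around the recorded null mean


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (direct convolution, no FFT shortcuts)
# ---------------------------------------------------------------------------

def _cwt_direct(x, fs, periods, omega0=6.0):
    """Oracle CWT: direct time-domain convolution with the sampled wavelet."""
    dt = 1.0 / fs
    n = len(x)
    ff = 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))
    out = np.empty((len(periods), n), complex)
    for i, p in enumerate(periods):
        s = p / ff
        for n0 in range(n):
            m = np.arange(n)
            eta = (m - n0) * dt / s
            psi = np.pi**-0.25 * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
            out[i, n0] = np.sum(x * np.sqrt(dt / s) * np.conj(psi))
    return out


def _smooth_direct(field, scales, fs, periods, sd_factor=1 / np.sqrt(2), octaves=0.6):
    """Oracle smoothing: explicit Gaussian kernel with reflected padding, then
    an explicit boxcar across scales with edge replication."""
    out = np.empty_like(field, dtype=float)
    for i, s in enumerate(scales):
        sigma = max(sd_factor * s * fs, 1e-9)
        r = int(6.0 * sigma + 0.5)
        t = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (t / sigma) ** 2)
        k /= k.sum()
        padded = np.pad(field[i], r, mode="symmetric") if r > 0 else field[i]
        out[i] = np.convolve(padded, k, mode="valid")
    if len(scales) > 1:
        dj = np.mean(np.diff(np.log2(periods)))
        nbox = max(1, int(round(octaves / dj)))
        if nbox > 1:
            left = nbox // 2
            right = nbox - 1 - left
            padded = np.vstack([np.repeat(out[:1], left, axis=0), out,
                                np.repeat(out[-1:], right, axis=0)])
            out = np.stack([padded[i:i + nbox].mean(axis=0) for i in range(len(scales))])
    return out


def test_brute_force_oracle_equivalence(rng):
    """FFT implementation vs direct-convolution oracle on 64-sample signals."""
    fs = 1.0
    n = 64
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    periods = W.period_grid(8, 16, voices_per_octave=6)
    cx = W.morlet_cwt(x, fs, periods)
    cy = W.morlet_cwt(y, fs, periods)

    dx = _cwt_direct(x, fs, periods)
    dy = _cwt_direct(y, fs, periods)
    scale_ref = np.abs(cx.coeffs).max()
    assert np.abs(cx.coeffs - dx).max() < 1e-6 * scale_ref
    assert np.abs(cy.coeffs - dy).max() < 1e-6 * scale_ref

    wm = W.compute_wtc(cx, cy)
    scales = cx.scales
    sxy = (_smooth_direct((dx * np.conj(dy)).real / scales[:, None], scales, fs, periods)
           + 1j * _smooth_direct((dx * np.conj(dy)).imag / scales[:, None], scales, fs, periods))
    sxx = _smooth_direct(np.abs(dx) ** 2 / scales[:, None], scales, fs, periods)
    syy = _smooth_direct(np.abs(dy) ** 2 / scales[:, None], scales, fs, periods)
    coh = np.clip(np.abs(sxy) ** 2 / (sxx * syy), 0, 1)
    assert np.abs(coh - wm.coherence).max() < 1e-6


# ---------------------------------------------------------------------------
# masked averaging
# ---------------------------------------------------------------------------

def _toy_wtc(coherence, periods, mask=None):
    if mask is None:
        mask = np.ones_like(coherence, dtype=bool)
    return W.WTCMatrix(coherence, periods, mask, (periods[0], periods[-1]), FS)


def test_mask_and_average_constant():
    periods = np.array([8.0, 16.0, 32.0])
    wm = _toy_wtc(np.full((3, 10), 0.5), periods)
    v, n = W.mask_and_average(wm)
    assert v == pytest.approx(0.5) and n == 30


def test_mask_and_average_all_coi():
    periods = np.array([8.0, 16.0])
    wm = _toy_wtc(np.full((2, 5), 0.5), periods, mask=np.zeros((2, 5), bool))
    v, n = W.mask_and_average(wm)
    assert np.isnan(v) and n == 0


def test_mask_and_average_checkerboard():
    periods = np.array([8.0, 16.0])
    coh = np.indices((2, 6)).sum(axis=0) % 2.0
    mask = np.ones((2, 6), bool)
    v, n = W.mask_and_average(_toy_wtc(coh, periods, mask))
    assert v == pytest.approx(0.5) and n == 12


def test_coi_mask_excludes_edges(rng):
    periods = W.period_grid(8, 40)
    c = W.morlet_cwt(rng.standard_normal(512), FS, periods)
    wm = W.compute_wtc(c, c)
    assert not wm.coi_mask[:, 0].any()          # edges fully inside COI
    assert wm.coi_mask[0, 256]                  # short periods valid mid-series
    # monotone: validity can only shrink with period
    assert np.all(wm.coi_mask[1:].sum(axis=1) <= wm.coi_mask[:-1].sum(axis=1))


# ---------------------------------------------------------------------------
# ROI pairs and dyad synchrony
# ---------------------------------------------------------------------------

def test_enumerate_roi_pairs_canonical():
    assert W.enumerate_roi_pairs(["IFGl", "IFGr", "TPJl", "TPJr"]) == [
        "IFGl_IFGl", "IFGr_IFGr", "TPJl_TPJl", "TPJr_TPJr", "IFGl_IFGr",
        "IFGl_TPJl", "IFGl_TPJr", "IFGr_TPJl", "IFGr_TPJr", "TPJl_TPJr",
    ]


@pytest.mark.parametrize("k, expected", [(1, 1), (2, 3), (4, 10)])
def test_enumerate_roi_pairs_count(k, expected):
    assert len(W.enumerate_roi_pairs([f"R{i}" for i in range(k)])) == expected


def test_dyad_synchrony_row_count(small_config):
    rec = generate_dyad_timeseries(small_config, 0, 0.5)
    table = W.dyad_synchrony(rec)
    # 1 phase x 2 intervals x 10 pairs
    assert len(table) == 20
    assert set(table["interval"]) == {"first", "second"}
    ok = table["wtc_value"].dropna()
    assert ((ok >= 0) & (ok <= 1)).all()


def test_dyad_synchrony_two_phase_count():
    cfg = SimulationConfig(n_dyads_per_condition=1,
                           phase_plan=(("manipulation", 300.0, 30.0),
                                       ("free_interaction", 300.0, 30.0)),
                           seed=3)
    rec = generate_dyad_timeseries(cfg, 0, 0.3)
    assert len(W.dyad_synchrony(rec)) == 40


def test_dyad_synchrony_identical_roi_signals(small_config):
    rec = generate_dyad_timeseries(small_config, 1, 0.4)
    for phase in rec.phases:
        rec.phases[phase][1] = rec.phases[phase][0]
    table = W.dyad_synchrony(rec, pairs=["IFGl_IFGl"])
    assert (table["wtc_value"] > 0.999).all()


def test_dyad_synchrony_bad_roi_marked_missing(small_config):
    rec = generate_dyad_timeseries(small_config, 2, 0.4)
    good = {ph: np.ones((2, 16), bool) for ph in rec.phases}
    rois = np.asarray(rec.channel_rois)
    for ph in good:
        good[ph][0, rois == "TPJl"] = False
    table = W.dyad_synchrony(rec, good_channels=good)
    involved = table["roi_pair"].str.contains("TPJl")
    assert table.loc[involved, "wtc_value"].isna().all()
    assert (table.loc[involved, "excluded_reason"] == "bad ROI").all()
    assert table.loc[~involved, "wtc_value"].notna().all()
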
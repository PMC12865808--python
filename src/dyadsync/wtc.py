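"""Wavelet transform coherence (WTC) for dyadic hyperscanning signals.

Interbrain synchrony between two participants' region-of-interest (ROI)
hemodynamic signals is quantified with magnitude-squared wavelet coherence
computed from analytic Morlet continuous wavelet transforms, smoothed in time
and scale, restricted to an adaptive period band (8 s up to one quarter of the
segment duration) and to the region of the time-scale plane outside the cone
of influence (COI), and finally averaged to one scalar per dyad x ROI pair x
phase x interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import convolve

__all__ = [
    "SegmentTooShortError",
    "CWTResult",
    "WTCMatrix",
    "adaptive_period_range",
    "period_grid",
    "morlet_cwt",
    "compute_wtc",
    "mask_and_average",
    "enumerate_roi_pairs",
    "dyad_synchrony",
    "DEFAULT_ROIS",
]

DEFAULT_ROIS = ("IFGl", "IFGr", "TPJl", "TPJr")

#: e-folding time of the Morlet wavelet envelope is sqrt(2) * scale
COI_EFOLD = np.sqrt(2.0)


class SegmentTooShortError(ValueError):
    """Segment too short for the requested minimum analysis period."""


def morlet_fourier_factor(omega0: float = 6.0) -> float:
    """Ratio Fourier period / wavelet scale for the analytic Morlet wavelet."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


def adaptive_period_range(duration_s: float, min_period_s: float = 8.0) -> tuple[float, float]:
    """Adaptive analysis band: from ``min_period_s`` to a quarter of the segment.

    The upper bound guarantees at least four cycles of the slowest analysed
    fluctuation inside the segment.  A 300 s segment therefore yields
    (8, 75) s, i.e. roughly 0.0133-0.125 Hz.
    """
    if duration_s <= 0:
        raise SegmentTooShortError(f"nonpositive segment duration {duration_s}")
    pmax = duration_s / 4.0
    if pmax < min_period_s:
        raise SegmentTooShortError(
            f"segment of {duration_s:g} s supports periods only up to {pmax:g} s, "
            f"below the minimum period {min_period_s:g} s"
        )
    return (float(min_period_s), float(pmax))


def period_grid(pmin_s: float, pmax_s: float, voices_per_octave: int = 12) -> np.ndarray:
    """Logarithmic period grid from pmin to pmax with ``voices_per_octave`` steps."""
    if pmin_s <= 0 or pmax_s < pmin_s:
        raise ValueError("need 0 < pmin_s <= pmax_s")
    n_oct = np.log2(pmax_s / pmin_s)
    n = int(np.floor(n_oct * voices_per_octave)) + 1
    periods = pmin_s * 2.0 ** (np.arange(n) / voices_per_octave)
    if periods[-1] < pmax_s * (1.0 - 1e-9):
        periods = np.append(periods, pmax_s)
    return periods


@dataclass
class CWTResult:
    """Continuous wavelet transform on a period grid.

    coeffs has shape (n_periods, n_samples); ``coi_period_s[t]`` is the longest
    period whose e-folding time fits between sample t and the nearer edge.
    """

    coeffs: np.ndarray
    periods_s: np.ndarray
    scales: np.ndarray
    coi_period_s: np.ndarray
    sampling_rate_hz: float
    omega0: float = 6.0
    _smoothed_power: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[1]

    def same_grid(self, other: "CWTResult") -> bool:
        return (
            self.coeffs.shape == other.coeffs.shape
            and np.allclose(self.periods_s, other.periods_s)
            and self.sampling_rate_hz == other.sampling_rate_hz
        )


@dataclass
class WTCMatrix:
    """Scale x time coherence in [0, 1] with period vector and COI mask."""

    coherence: np.ndarray
    periods_s: np.ndarray
    coi_mask: np.ndarray  # True = outside the COI (valid)
    period_band_s: tuple[float, float]
    sampling_rate_hz: float


def morlet_cwt(
    x: np.ndarray,
    fs: float,
    periods_s: np.ndarray,
    omega0: float = 6.0,
) -> CWTResult:
    """Analytic Morlet CWT at the scales corresponding to ``periods_s``.

    Uses the frequency-domain formulation with zero padding generous enough
    that circular wraparound is negligible at the largest scale; the result is
    the discretised linear convolution of the signal (zero-extended) with the
    scaled analytic Morlet wavelet, normalised so that unit-amplitude
    sinusoids give scale-independent peak magnitude ``sqrt(2 pi s / dt)/pi^(1/4)``
    envelopes (Torrence-Compo convention).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or infinite values")
    periods_s = np.asarray(periods_s, dtype=float)
    if np.any(np.diff(periods_s) <= 0) and periods_s.size > 1:
        raise ValueError("periods_s must be strictly increasing")
    n = x.size
    dt = 1.0 / fs
    ff = morlet_fourier_factor(omega0)
    scales = periods_s / ff

    # pad so the largest wavelet (e-fold support ~ +-4 sqrt(2) s) cannot wrap
    pad_target = n + int(np.ceil(8.0 * scales.max() / dt))
    n_pad = 1 << int(np.ceil(np.log2(max(pad_target, 2))))
    xh = np.fft.fft(x, n=n_pad)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    norm = np.pi**-0.25 * np.sqrt(2.0 * np.pi * scales / dt)
    coeffs = np.empty((scales.size, n), dtype=complex)
    pos = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = norm[i] * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        coeffs[i] = np.fft.ifft(xh * psi_hat)[:n]

    t_idx = np.arange(n, dtype=float)
    edge_s = np.minimum(t_idx, n - 1 - t_idx) * dt
    coi_period_s = edge_s * ff / COI_EFOLD
    return CWTResult(coeffs, periods_s, scales, coi_period_s, fs, omega0)


def _smooth(
    field2d: np.ndarray,
    scales: np.ndarray,
    fs: float,
    periods_s: np.ndarray,
    time_smooth_sd_scales: float = 1.0 / np.sqrt(2.0),
    scale_smooth_octaves: float = 0.6,
) -> np.ndarray:
    """WTC smoothing operator: Gaussian in time per scale, boxcar across scale.

    The Gaussian is truncated at 6 SD and applied with symmetric (reflect)
    boundary handling via FFT convolution — the kernels at coarse scales span
    thousands of samples, where direct convolution is prohibitively slow.
    """
    out = np.empty_like(field2d, dtype=float)
    for i, s in enumerate(scales):
        sigma = max(time_smooth_sd_scales * s * fs, 1e-9)
        r = int(6.0 * sigma + 0.5)
        row = field2d[i].astype(float)
        if r < 1:
            out[i] = row
        else:
            t = np.arange(-r, r + 1)
            k = np.exp(-0.5 * (t / sigma) ** 2)
            k /= k.sum()
            padded = np.pad(row, r, mode="symmetric")
            out[i] = convolve(padded, k, mode="valid", method="auto")
    if scales.size > 1:
        dj = np.mean(np.diff(np.log2(periods_s)))
        nbox = max(1, int(round(scale_smooth_octaves / dj)))
        if nbox > 1:
            out = uniform_filter1d(out, nbox, axis=0, mode="nearest")
    return out


def _smooth_complex(cross: np.ndarray, scales, fs, periods_s, **kw) -> np.ndarray:
    return _smooth(cross.real, scales, fs, periods_s, **kw) + 1j * _smooth(
        cross.imag, scales, fs, periods_s, **kw
    )


def _smoothed_power(c: CWTResult, **kw) -> np.ndarray:
    """Scale-normalised smoothed auto power |W|^2 / s (cached on the CWTResult)."""
    if c._smoothed_power is None:
        w = np.abs(c.coeffs) ** 2 / c.scales[:, None]
        c._smoothed_power = _smooth(w, c.scales, c.sampling_rate_hz, c.periods_s, **kw)
    return c._smoothed_power


def compute_wtc(
    cx: CWTResult,
    cy: CWTResult,
    period_band_s: tuple[float, float] | None = None,
    time_smooth_sd_scales: float = 1.0 / np.sqrt(2.0),
    scale_smooth_octaves: float = 0.6,
) -> WTCMatrix:
    """Magnitude-squared wavelet coherence between two transforms.

    R^2 = |S(s^-1 Wxy)|^2 / (S(s^-1 |Wx|^2) S(s^-1 |Wy|^2)) with S the
    time-then-scale smoothing of :func:`_smooth`.  Values are clipped to [0, 1]
    (the unclipped values respect the bound up to numerical tolerance by the
    Cauchy-Schwarz inequality, since the same S is applied to all three terms).
    """
    if not cx.same_grid(cy):
        raise ValueError("CWT grids (periods, length, sampling rate) must match")
    kw = dict(
        time_smooth_sd_scales=time_smooth_sd_scales,
        scale_smooth_octaves=scale_smooth_octaves,
    )
    scales, fs, periods = cx.scales, cx.sampling_rate_hz, cx.periods_s
    sxy = _smooth_complex(cx.coeffs * np.conj(cy.coeffs) / scales[:, None], scales, fs, periods, **kw)
    sxx = _smoothed_power(cx, **kw)
    syy = _smoothed_power(cy, **kw)
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    coi_mask = periods[:, None] <= np.minimum(cx.coi_period_s, cy.coi_period_s)[None, :]
    band = period_band_s if period_band_s is not None else (float(periods[0]), float(periods[-1]))
    return WTCMatrix(coh, periods, coi_mask, band, fs)


def mask_and_average(
    wtc: WTCMatrix, band: tuple[float, float] | None = None
) -> tuple[float, int]:
    """Mean coherence over in-band cells outside the COI.

    Returns ``(value, n_valid_cells)``; value is NaN when every in-band cell
    falls inside the COI (reason: fully inside COI).
    """
    if band is None:
        band = wtc.period_band_s
    pmin, pmax = band
    in_band = (wtc.periods_s >= pmin - 1e-12) & (wtc.periods_s <= pmax + 1e-12)
    if not in_band.any():
        raise ValueError(f"band {band} lies outside the computed period grid")
    valid = wtc.coi_mask[in_band]
    vals = wtc.coherence[in_band]
    n_valid = int(valid.sum())
    if n_valid == 0:
        return (float("nan"), 0)
    return (float(vals[valid].mean()), n_valid)


def enumerate_roi_pairs(rois: Sequence[str] = DEFAULT_ROIS) -> list[str]:
    """All unordered ROI pairs with repetition: homologous pairs first (in ROI
    order), then cross pairs in row-major upper-triangle order.

    For the canonical four ROIs this yields the ten pairs
    IFGl_IFGl, IFGr_IFGr, TPJl_TPJl, TPJr_TPJr, IFGl_IFGr, IFGl_TPJl,
    IFGl_TPJr, IFGr_TPJl, IFGr_TPJr, TPJl_TPJr.
    """
    rois = list(rois)
    if not rois:
        raise ValueError("ROI list is empty")
    pairs = [f"{r}_{r}" for r in rois]
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            pairs.append(f"{rois[i]}_{rois[j]}")
    return pairs


def split_pair(pair: str) -> tuple[str, str]:
    a, b = pair.split("_")
    return a, b


def roi_signals(data: np.ndarray, channel_rois: Sequence[str], good: np.ndarray | None = None):
    """Average channels into ROI signals.

    data: (n_channels, n_samples); channel_rois names each channel's ROI;
    good: optional boolean per channel.  Returns dict roi -> 1-D signal or
    None when an ROI has no good channel.
    """
    channel_rois = np.asarray(channel_rois)
    if good is None:
        good = np.ones(data.shape[0], dtype=bool)
    out = {}
    for roi in dict.fromkeys(channel_rois.tolist()):
        sel = (channel_rois == roi) & good
        out[roi] = data[sel].mean(axis=0) if sel.any() else None
    return out


def _interval_slices(n_samples: int, n_intervals: int = 2) -> list[slice]:
    edges = np.linspace(0, n_samples, n_intervals + 1).astype(int)
    return [slice(edges[k], edges[k + 1]) for k in range(n_intervals)]

INTERVAL_LABELS = ("first", "second")


def dyad_synchrony(
    recording,
    channel_rois: Sequence[str] | None = None,
    good_channels: dict | None = None,
    pairs: Iterable[str] | None = None,
    min_period_s: float = 8.0,
    voices_per_octave: int = 12,
    n_intervals: int = 2,
    channels_first: bool = True,
):
    """One synchrony scalar per ROI pair x phase x interval for one dyad.

    ``recording`` must expose ``dyad_id``, ``sampling_rate_hz``,
    ``channel_rois`` and ``phases`` (mapping phase label -> array of shape
    (2, n_channels, n_samples)), as produced by the synthetic-data generator
    or assembled from preprocessed HbO tables.  Each phase is split into
    ``n_intervals`` equal intervals; the adaptive period band is applied per
    interval; heterologous pairs average the two cross-assignments
    (participants are exchangeable).

    With ``channels_first`` (default) channels are averaged into one ROI
    signal before the transform; otherwise coherence is computed per channel
    pair within the ROI pair and the scalars averaged.

    Returns a list of row dicts (long format).
    """
    import pandas as pd  # local import keeps module import light

    fs = recording.sampling_rate_hz
    if channel_rois is None:
        channel_rois = recording.channel_rois
    rois = list(dict.fromkeys(channel_rois))
    pair_list = list(pairs) if pairs is not None else enumerate_roi_pairs(rois)
    rows = []
    for phase, data in recording.phases.items():
        good = None if good_channels is None else good_channels.get(phase)
        for k, sl in enumerate(_interval_slices(data.shape[2], n_intervals)):
            label = INTERVAL_LABELS[k] if k < len(INTERVAL_LABELS) else str(k)
            seg = data[:, :, sl]
            duration = seg.shape[2] / fs
            try:
                band = adaptive_period_range(duration, min_period_s)
            except SegmentTooShortError as err:
                for pair in pair_list:
                    rows.append(_row(recording.dyad_id, pair, phase, label, np.nan, 0, str(err)))
                continue
            periods = period_grid(*band, voices_per_octave)
            if channels_first:
                sigs = [
                    roi_signals(seg[p], channel_rois, None if good is None else good[p])
                    for p in (0, 1)
                ]
                cwts = [
                    {r: (morlet_cwt(s[r], fs, periods) if s[r] is not None else None) for r in rois}
                    for s in sigs
                ]
                for pair in pair_list:
                    a, b = split_pair(pair)
                    if any(cwts[p][r] is None for p in (0, 1) for r in {a, b}):
                        rows.append(_row(recording.dyad_id, pair, phase, label,
                                         np.nan, 0, "bad ROI"))
                        continue
                    vals, ncells, reason = [], 0, None
                    combos = [(a, b)] if a == b else [(a, b), (b, a)]
                    for ra, rb in combos:
                        v, nc = mask_and_average(compute_wtc(cwts[0][ra], cwts[1][rb]), band)
                        if np.isnan(v):
                            reason = "fully inside COI"
                        else:
                            vals.append(v)
                            ncells += nc
                    if vals:
                        rows.append(_row(recording.dyad_id, pair, phase, label,
                                         float(np.mean(vals)), ncells, None))
                    else:
                        rows.append(_row(recording.dyad_id, pair, phase, label,
                                         np.nan, 0, reason or "bad ROI"))
            else:
                rows.extend(
                    _channelwise_pairs(recording.dyad_id, seg, channel_rois, good,
                                       pair_list, phase, label, fs, periods, band)
                )
    return pd.DataFrame(rows, columns=["dyad_id", "roi_pair", "phase", "interval",
                                       "wtc_value", "n_valid_cells", "excluded_reason"])


def _row(dyad_id, pair, phase, interval, value, n_valid, reason):
    return {
        "dyad_id": dyad_id, "roi_pair": pair, "phase": phase, "interval": interval,
        "wtc_value": value, "n_valid_cells": n_valid, "excluded_reason": reason,
    }


def _channelwise_pairs(dyad_id, seg, channel_rois, good, pair_list, phase, label, fs, periods, band):
    channel_rois = np.asarray(channel_rois)
    rows = []
    cache: dict[tuple[int, int], CWTResult] = {}

    def cwt_of(p, ch):
        key = (p, ch)
        if key not in cache:
            cache[key] = morlet_cwt(seg[p, ch], fs, periods)
        return cache[key]

    for pair in pair_list:
        a, b = split_pair(pair)
        vals, ncells = [], 0
        combos = [(a, b)] if a == b else [(a, b), (b, a)]
        for ra, rb in combos:
            for i in np.flatnonzero((channel_rois == ra) & (good[0] if good is not None else True)):
                for j in np.flatnonzero((channel_rois == rb) & (good[1] if good is not None else True)):
                    v, nc = mask_and_average(compute_wtc(cwt_of(0, i), cwt_of(1, j)), band)
                    if not np.isnan(v):
                        vals.append(v)
                        ncells += nc
        if vals:
            rows.append(_row(dyad_id, pair, phase, label, float(np.mean(vals)), ncells, None))
        else:
            rows.append(_row(dyad_id, pair, phase, label, np.nan, 0, "no valid channel pair"))
    return rows
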
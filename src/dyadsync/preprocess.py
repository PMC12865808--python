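"""fNIRS preprocessing: raw intensity -> optical density -> motion handling ->
filtering -> hemoglobin concentration.

A compact, auditable chain with the standard step order
intensity -> OD -> motion detection -> spline correction -> wavelet filtering
-> band-pass -> modified Beer-Lambert law (MBLL), plus channel/ROI/dyad
quality bookkeeping.  All thresholds are explicit keyword parameters with
package defaults; no step changes series length or sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d

__all__ = [
    "RawIntensity",
    "OpticalDensity",
    "HbConcentration",
    "intensity_to_od",
    "detect_motion",
    "spline_correct",
    "wavelet_filter",
    "bandpass",
    "mbll",
    "mbll_forward",
    "channel_quality",
    "roi_quality",
    "dyad_roi_pair_exclusions",
    "preprocess_intensity",
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
    "DEFAULT_DISTANCE_CM",
]

#: extinction coefficients [wavelength, chromophore] for 760/850 nm,
#: columns (HbO, HbR), units 1/(cm * M); standard tabulated values, overridable
DEFAULT_EXTINCTION = np.array([[1486.6, 3843.7],   # 760 nm
                               [2526.4, 1798.6]])  # 850 nm
DEFAULT_DPF = (6.0, 6.0)
DEFAULT_DISTANCE_CM = 3.0


@dataclass
class RawIntensity:
    """Two-wavelength raw light intensity, shape (2, n_channels, n_samples)."""

    intensity: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[0] != 2:
            raise ValueError("intensity must have shape (2, n_channels, n_samples)")


@dataclass
class OpticalDensity:
    """Optical density per wavelength, shape (2, n_channels, n_samples)."""

    od: np.ndarray
    sampling_rate_hz: float
    artifact_mask: np.ndarray | None = None  # (n_channels, n_samples) boolean
    bad_channels: np.ndarray | None = None   # (n_channels,) boolean

    def copy(self) -> "OpticalDensity":
        return OpticalDensity(self.od.copy(), self.sampling_rate_hz,
                              None if self.artifact_mask is None else self.artifact_mask.copy(),
                              None if self.bad_channels is None else self.bad_channels.copy())


@dataclass
class HbConcentration:
    """Concentration changes, shapes (n_channels, n_samples) each."""

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate_hz: float
    quality_flags: np.ndarray | None = None  # True = bad channel


def intensity_to_od(raw: RawIntensity) -> OpticalDensity:
    """OD(t) = -log10(I(t) / mean(I)) per channel per wavelength."""
    bad = np.argwhere(raw.intensity <= 0)
    if bad.size:
        w, c, s = bad[0]
        raise ValueError(
            f"nonpositive intensity at wavelength {w}, channel {c}, sample {s}"
        )
    mean = raw.intensity.mean(axis=2, keepdims=True)
    od = -np.log10(raw.intensity / mean)
    return OpticalDensity(od, raw.sampling_rate_hz)


def detect_motion(od: OpticalDensity, window_s: float = 1.0,
                  sd_factor: float = 13.5, amp_thresh: float = 0.4) -> np.ndarray:
    """Flag samples whose moving-window signal change is an outlier.

    A sample is flagged when the within-window peak-to-peak change exceeds
    ``sd_factor`` times the channel's sample-to-sample SD or ``amp_thresh``
    in absolute value; flags are dilated to whole windows.  The per-channel
    mask is the union over the two wavelengths.
    """
    fs = od.sampling_rate_hz
    w = max(2, int(round(window_s * fs)))
    x = od.od
    ptp = maximum_filter1d(x, w, axis=2) - minimum_filter1d(x, w, axis=2)
    dstd = np.diff(x, axis=2).std(axis=2, ddof=1, keepdims=True)  # (2, n_ch, 1)
    flagged = (ptp > sd_factor * dstd) | (ptp > amp_thresh)
    mask = flagged.any(axis=0)
    return binary_dilation(mask, structure=np.ones((1, w), dtype=bool))


def _segments(mask_1d: np.ndarray):
    idx = np.flatnonzero(mask_1d)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, ends)


def spline_correct(od: OpticalDensity, mask: np.ndarray,
                   smoothing: float = 0.99) -> OpticalDensity:
    """Remove the artifact trend inside flagged segments (spline correction).

    Within each flagged segment the signal's smoothing-spline trend is
    subtracted (anchored at the segment's first trend value) and the remaining
    trend offset is propagated to all subsequent samples, so baseline shifts
    caused by the artifact are removed and segment boundaries stay continuous.
    Unflagged channels pass through unchanged; a fully-flagged channel is
    marked bad and passed through.
    """
    if mask.shape != od.od.shape[1:]:
        raise ValueError("mask must have shape (n_channels, n_samples)")
    out = od.copy()
    n_ch, n = mask.shape
    bad = np.zeros(n_ch, dtype=bool)
    lam = (1.0 - smoothing) / max(smoothing, 1e-12)
    for c in range(n_ch):
        if not mask[c].any():
            continue
        if mask[c].all():
            bad[c] = True
            continue
        for w in range(2):
            x = out.od[w, c]
            for i0, i1 in _segments(mask[c]):
                seg = x[i0:i1].copy()
                t = np.arange(i0, i1, dtype=float)
                if i1 - i0 >= 4:
                    trend = make_smoothing_spline(t, seg, lam=lam)(t)
                else:
                    trend = np.linspace(seg[0], seg[-1], i1 - i0)
                # subtract within-segment trend variation, anchor at the left
                # edge, and propagate the removed offset to the tail
                x[i0:i1] = seg - (trend - trend[0])
                x[i1:] -= trend[-1] - trend[0]
    out.artifact_mask = mask
    out.bad_channels = bad if od.bad_channels is None else (od.bad_channels | bad)
    return out


def wavelet_filter(od: OpticalDensity, iqr_factor: float = 1.5,
                   wavelet: str = "db2") -> OpticalDensity:
    """Zero outlying detail coefficients of a discrete wavelet decomposition.

    Per channel and wavelength, detail coefficients farther than
    ``iqr_factor`` interquartile ranges from their level's median are set to
    zero before reconstruction; motion transients live in such outliers while
    slow hemodynamics stay in the approximation and the bulk of the details.
    """
    out = od.copy()
    n = od.od.shape[2]
    for w in range(od.od.shape[0]):
        for c in range(od.od.shape[1]):
            x = od.od[w, c]
            coeffs = pywt.wavedec(x, wavelet, mode="periodization")
            for lev in range(1, len(coeffs)):
                d = coeffs[lev]
                if d.size < 4 or not np.isfinite(iqr_factor):
                    continue
                q1, med, q3 = np.percentile(d, [25, 50, 75])
                iqr = q3 - q1
                outlier = np.abs(d - med) > iqr_factor * iqr
                d[outlier] = 0.0
            rec = pywt.waverec(coeffs, wavelet, mode="periodization")
            out.od[w, c] = rec[:n]
    return out


def bandpass(od: OpticalDensity, low_hz: float = 0.01, high_hz: float = 0.5,
             order: int = 3) -> OpticalDensity:
    """Zero-phase Butterworth band-pass (low_hz = 0 gives a pure low-pass)."""
    fs = od.sampling_rate_hz
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz <= nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for Nyquist {nyq}")
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    out = od.copy()
    out.od = signal.sosfiltfilt(sos, od.od, axis=2)
    return out


def _mbll_matrix(extinction, dpf, distance_cm) -> np.ndarray:
    ext = np.asarray(extinction, dtype=float)
    if ext.shape != (2, 2):
        raise ValueError("extinction must be a 2x2 matrix (wavelength x chromophore)")
    a = ext * (np.asarray(dpf, dtype=float)[:, None] * distance_cm)
    if abs(np.linalg.det(a)) < 1e-30:
        raise ValueError("extinction system is singular; cannot separate HbO/HbR")
    return a


def mbll(od: OpticalDensity, dpf=DEFAULT_DPF, extinction=DEFAULT_EXTINCTION,
         distance_cm: float = DEFAULT_DISTANCE_CM) -> HbConcentration:
    """Solve the 2x2 modified Beer-Lambert system per sample.

    delta-OD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * DPF_lambda
    """
    if min(dpf) <= 0 or distance_cm <= 0:
        raise ValueError("DPF and distance must be positive")
    a = _mbll_matrix(extinction, dpf, distance_cm)
    inv = np.linalg.inv(a)
    flat = od.od.reshape(2, -1)
    conc = inv @ flat
    shape = od.od.shape[1:]
    return HbConcentration(conc[0].reshape(shape), conc[1].reshape(shape),
                           od.sampling_rate_hz, quality_flags=od.bad_channels)


def mbll_forward(hbo: np.ndarray, hbr: np.ndarray, dpf=DEFAULT_DPF,
                 extinction=DEFAULT_EXTINCTION,
                 distance_cm: float = DEFAULT_DISTANCE_CM) -> np.ndarray:
    """Forward MBLL: (dHbO, dHbR) -> delta-OD at both wavelengths."""
    a = _mbll_matrix(extinction, dpf, distance_cm)
    stacked = np.stack([np.asarray(hbo), np.asarray(hbr)])
    return np.tensordot(a, stacked, axes=(1, 0))


def channel_quality(raw: RawIntensity, cv_thresh: float = 0.15,
                    flat_tol: float = 1e-12) -> np.ndarray:
    """Boolean bad-channel flags from raw intensity.

    A channel is bad when, at either wavelength, the coefficient of variation
    exceeds ``cv_thresh`` or the signal is flat/saturated (zero variation).
    """
    if cv_thresh <= 0:
        raise ValueError("cv_thresh must be positive")
    mean = raw.intensity.mean(axis=2)
    sd = raw.intensity.std(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    bad = (cv > cv_thresh) | (sd <= flat_tol)
    return bad.any(axis=0)


def roi_quality(bad_channels: np.ndarray, channel_rois) -> dict[str, bool]:
    """An ROI is bad when all of its channels are bad."""
    channel_rois = np.asarray(channel_rois)
    return {roi: bool(bad_channels[channel_rois == roi].all())
            for roi in dict.fromkeys(channel_rois.tolist())}


def dyad_roi_pair_exclusions(roi_bad_a: dict[str, bool], roi_bad_b: dict[str, bool],
                             roi_pairs) -> dict[str, bool]:
    """A dyad is excluded for an ROI pair when either member's ROI is bad.

    For a heterologous pair both cross-assignments enter the pair average, so
    the pair is excluded when any involved ROI of either member is bad.
    """
    out = {}
    for pair in roi_pairs:
        a, b = pair.split("_")
        out[pair] = bool(roi_bad_a[a] or roi_bad_a[b] or roi_bad_b[a] or roi_bad_b[b])
    return out


@dataclass
class PreprocessParams:
    """Defaults for the fixed-order preprocessing chain."""

    motion_window_s: float = 1.0
    motion_sd_factor: float = 13.5
    motion_amp_thresh: float = 0.4
    spline_smoothing: float = 0.99
    wavelet_iqr_factor: float = 1.5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.5
    cv_thresh: float = 0.15
    dpf: tuple = DEFAULT_DPF
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    distance_cm: float = DEFAULT_DISTANCE_CM


def preprocess_intensity(raw: RawIntensity, params: PreprocessParams | None = None,
                         log: list | None = None) -> HbConcentration:
    """Run the fixed chain intensity -> OD -> motion -> spline -> wavelet ->
    band-pass -> MBLL and attach channel quality flags."""
    p = params or PreprocessParams()
    steps = ["intensity_to_od", "detect_motion", "spline_correct",
             "wavelet_filter", "bandpass", "mbll"]
    if log is not None:
        log.extend(steps)
    quality = channel_quality(raw, p.cv_thresh)
    od = intensity_to_od(raw)
    mask = detect_motion(od, p.motion_window_s, p.motion_sd_factor, p.motion_amp_thresh)
    od = spline_correct(od, mask, p.spline_smoothing)
    od = wavelet_filter(od, p.wavelet_iqr_factor)
    od = bandpass(od, p.band_low_hz, p.band_high_hz)
    hb = mbll(od, p.dpf, p.extinction, p.distance_cm)
    hb.quality_flags = quality | (od.bad_channels if od.bad_channels is not None else False)
    return hb
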
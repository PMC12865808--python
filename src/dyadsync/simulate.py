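"""Synthetic dyadic fNIRS cohorts with known ground truth.

Generates everything the analysis chain consumes without any download: paired
two-participant multi-channel hemodynamic recordings with a tunable cross-brain
coupling in a low-frequency period band, physiological nuisance components
(cardiac, respiratory, Mayer waves, 1/f background, optional motion spikes),
per-participant laughter annotation tracks whose per-condition dyad-union
totals are calibrated to the published per-cell means, and questionnaire
outcome tables produced by a linear treatment -> mediator -> outcome structural
model.

Design emulated: a 2 x 2 between-dyad design (Laughter yes/no x Social context
yes/no), a ~10-min manipulation phase and a ~10-min free-interaction phase
sampled at 7.81 Hz, four ROIs (bilateral IFG and TPJ) with four channels each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .wtc import DEFAULT_ROIS

__all__ = [
    "NoiseComponent",
    "SimulationConfig",
    "StructuralParams",
    "BoutParams",
    "DyadRecording",
    "Cohort",
    "CONDITIONS",
    "TABLE1_UNION_MEAN_S",
    "bout_params_for",
    "generate_dyad_timeseries",
    "generate_laughter_bouts",
    "generate_outcomes",
    "generate_cohort",
    "bandlimited_noise",
    "recording_to_intensity",
]

#: 2x2 cells as (laughter, social) flags, in a fixed enumeration order
CONDITIONS = ((True, True), (True, False), (False, True), (False, False))

CONDITION_LABELS = {
    (True, True): "laughter_social",
    (True, False): "laughter_nosocial",
    (False, True): "nolaughter_social",
    (False, False): "nolaughter_nosocial",
}

#: published per-cell dyad-union laughter totals (seconds) used as the
#: calibration surface for the bout-process defaults
TABLE1_UNION_MEAN_S = {
    ("manipulation", True, True): 135.00,
    ("manipulation", True, False): 51.20,
    ("manipulation", False, True): 36.10,
    ("manipulation", False, False): 0.52,
    ("free_interaction", True, True): 51.20,
    ("free_interaction", True, False): 47.60,
    ("free_interaction", False, True): 50.20,
    ("free_interaction", False, False): 50.40,
}


@dataclass(frozen=True)
class NoiseComponent:
    """A narrowband physiological nuisance sinusoid."""

    center_freq_hz: float
    amplitude: float
    jitter: float  # relative SD of the per-participant frequency perturbation


DEFAULT_NOISE = (
    NoiseComponent(1.0, 0.30, 0.02),   # cardiac
    NoiseComponent(0.25, 0.20, 0.02),  # respiratory
    NoiseComponent(0.10, 0.15, 0.01),  # Mayer waves
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator configuration.

    phase_plan entries are (label, task duration s, pre-onset window s); the
    pre-onset window is the inter-task gap assigned to the subsequent phase for
    laughter bookkeeping.  coupling_strength may be a single kappa applied to
    every condition or a mapping {(laughter, social): kappa}.
    """

    n_dyads_per_condition: int = 24
    sampling_rate_hz: float = 7.81
    phase_plan: tuple = (("manipulation", 600.0, 282.0), ("free_interaction", 600.0, 60.0))
    coupling_period_band_s: tuple[float, float] = (8.0, 75.0)
    coupling_strength: float | Mapping[tuple[bool, bool], float] = 0.3
    noise_components: tuple[NoiseComponent, ...] = DEFAULT_NOISE
    background_slope: float = 1.0
    background_amplitude: float = 0.5
    channel_noise_sd: float = 0.3
    motion_rate_per_min: float = 0.0
    rois: tuple[str, ...] = DEFAULT_ROIS
    channels_per_roi: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_dyads_per_condition <= 0:
            raise ValueError("n_dyads_per_condition must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        lo, hi = self.coupling_period_band_s
        if not (8.0 <= lo <= hi <= 75.0 + 1e-9) and not (0 < lo <= hi):
            raise ValueError("coupling band must satisfy 0 < low <= high")
        if self.motion_rate_per_min < 0:
            raise ValueError("motion_rate_per_min must be nonnegative")
        for label, dur, pre in self.phase_plan:
            if dur <= 0 or pre < 0:
                raise ValueError(f"phase {label}: durations must be positive")
            if hi > dur / 4.0:
                raise ValueError(
                    f"coupling band upper bound {hi:g} s exceeds a quarter of the "
                    f"{label} phase duration ({dur:g} s)"
                )
        for k in self._kappas().values():
            if not 0.0 <= k <= 1.0:
                raise ValueError("coupling strength kappa must lie in [0, 1]")

    def _kappas(self) -> dict[tuple[bool, bool], float]:
        ks = self.coupling_strength
        if isinstance(ks, Mapping):
            return {c: float(ks[c]) for c in CONDITIONS}
        return {c: float(ks) for c in CONDITIONS}

    def kappa_for(self, laughter: bool, social: bool) -> float:
        return self._kappas()[(bool(laughter), bool(social))]

    @property
    def n_channels(self) -> int:
        return len(self.rois) * self.channels_per_roi

    @property
    def channel_rois(self) -> tuple[str, ...]:
        return tuple(r for r in self.rois for _ in range(self.channels_per_roi))

    def rng(self, *stream) -> np.random.Generator:
        """Documented seed-splitting rule: one master seed, per-purpose substreams.

        Children are spawned as SeedSequence([master_seed, *stream]); identical
        (config, stream) therefore always yields identical output regardless of
        call order.
        """
        key = [int(self.seed)] + [int(s) for s in stream]
        return np.random.default_rng(np.random.SeedSequence(key))


@dataclass(frozen=True)
class StructuralParams:
    """Linear structural links treatment -> mediator -> outcome.

    a_path: treatment -> mediator; b_path: mediator -> outcome; c_prime:
    direct treatment -> outcome.  Defaults are null paths: the emulated study
    found no overall mediation, so the baseline cohort carries no planted
    effect; tests and planted-signal checks pass explicit values.
    """

    a_path: float = 0.0
    b_path: float = 0.0
    c_prime: float = 0.0
    sd_mediator_noise: float = 1.0
    sd_outcome_noise: float = 1.0

    def __post_init__(self):
        if self.sd_mediator_noise <= 0 or self.sd_outcome_noise <= 0:
            raise ValueError("noise SDs must be positive")


@dataclass(frozen=True)
class BoutParams:
    """Poisson-onset, log-normal-duration laughter bout process (one participant)."""

    rate_per_s: float
    mean_duration_s: float = 3.0
    sigma_log: float = 0.6

    def __post_init__(self):
        if self.rate_per_s < 0:
            raise ValueError("bout rate must be nonnegative")
        if self.mean_duration_s <= 0:
            raise ValueError("mean bout duration must be positive")


def bout_params_for(config: SimulationConfig, phase: str, laughter: bool, social: bool) -> BoutParams:
    """Per-condition bout defaults calibrated to the published dyad-union means.

    With bout onsets a homogeneous Poisson process of rate lambda and i.i.d.
    durations of mean mu, the stationary fraction of time a participant laughs
    is p = 1 - exp(-lambda mu) (M/G/infinity busy fraction) and the dyad-union
    fraction of two independent participants is q = 1 - (1 - p)^2.  Inverting
    q = target / window gives the default rate analytically.
    """
    window = _extended_window_s(config, phase)
    target = TABLE1_UNION_MEAN_S[(phase, bool(laughter), bool(social))]
    q = min(target / window, 0.999)
    p = 1.0 - math.sqrt(1.0 - q)
    mu = 3.0
    rate = -math.log(1.0 - p) / mu if p > 0 else 0.0
    return BoutParams(rate_per_s=rate, mean_duration_s=mu, sigma_log=0.6)


def _extended_window_s(config: SimulationConfig, phase: str) -> float:
    for label, dur, pre in config.phase_plan:
        if label == phase:
            return dur + pre
    raise KeyError(f"unknown phase {phase!r}")


def phase_windows(config: SimulationConfig):
    """Chronological session layout: each task preceded by its pre-onset gap.

    Returns a list of (label, start_s, end_s, preonset_s) with absolute session
    times; the recording covers [start_s, end_s), the laughter window
    [start_s - preonset_s, end_s).
    """
    t = 0.0
    out = []
    for label, dur, pre in config.phase_plan:
        start = t + pre
        out.append((label, start, start + dur, pre))
        t = start + dur
    return out


@dataclass
class DyadRecording:
    """Two participants' multi-channel hemodynamic time series for each phase."""

    dyad_id: int
    laughter: bool
    social: bool
    kappa: float
    sampling_rate_hz: float
    channel_rois: tuple[str, ...]
    phases: dict[str, np.ndarray]  # label -> (2, n_channels, n_samples)

    @property
    def condition(self) -> str:
        return CONDITION_LABELS[(self.laughter, self.social)]


def bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                      period_band_s: tuple[float, float]) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed (hard spectral mask) to a period band."""
    lo_s, hi_s = period_band_s
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= 1.0 / hi_s) & (f <= 1.0 / lo_s)
    if not mask.any():
        raise ValueError("period band contains no Fourier bin at this length")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(rng: np.random.Generator, n: int, slope: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-slope / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_dyad_timeseries(config: SimulationConfig, dyad_index: int,
                             kappa: float, laughter: bool = True,
                             social: bool = True) -> DyadRecording:
    """Simulate one dyad's recording.

    Each channel is kappa * (shared band-limited dyad component)
    + sqrt(1 - kappa^2) * (independent band-limited ROI component)
    + 1/f background + physiological sinusoids with participant-specific random
    phases + channel noise + optional motion spikes.  Channels within an ROI
    share the ROI's latent component and differ only by channel noise, so the
    cross-brain coherence of ROI-averaged signals in the coupling band is an
    increasing function of kappa.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    fs = config.sampling_rate_hz
    band = config.coupling_period_band_s
    phases: dict[str, np.ndarray] = {}
    for pi, (label, dur, _pre) in enumerate(config.phase_plan):
        n = int(round(dur * fs))
        rng = config.rng(dyad_index, 100 + pi)
        shared = bandlimited_noise(rng, n, fs, band)
        data = np.zeros((2, config.n_channels, n))
        for p in (0, 1):
            prng = config.rng(dyad_index, 200 + pi, p)
            phys = np.zeros(n)
            t = np.arange(n) / fs
            for comp in config.noise_components:
                freq = comp.center_freq_hz * (1.0 + comp.jitter * prng.standard_normal())
                phase0 = prng.uniform(0, 2 * np.pi)
                phys += comp.amplitude * np.sin(2 * np.pi * freq * t + phase0)
            ch = 0
            for _roi in config.rois:
                indep = bandlimited_noise(prng, n, fs, band)
                latent = kappa * shared + math.sqrt(max(0.0, 1.0 - kappa**2)) * indep
                for _c in range(config.channels_per_roi):
                    bg = config.background_amplitude * _one_over_f_noise(prng, n, config.background_slope)
                    chn = config.channel_noise_sd * prng.standard_normal(n)
                    data[p, ch] = latent + phys + bg + chn
                    ch += 1
            if config.motion_rate_per_min > 0:
                _add_motion(data[p], prng, fs, config.motion_rate_per_min)
        phases[label] = data
    return DyadRecording(dyad_index, bool(laughter), bool(social), float(kappa),
                         fs, config.channel_rois, phases)


def _add_motion(data: np.ndarray, rng: np.random.Generator, fs: float, rate_per_min: float):
    n = data.shape[1]
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    t = np.arange(n)
    for _ in range(n_events):
        center = rng.integers(0, n)
        width = max(1.0, 0.5 * fs)
        amp = rng.uniform(3.0, 8.0) * data.std()
        spike = amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        data += spike[None, :]  # jaw-movement-like: hits all channels


def generate_laughter_bouts(config: SimulationConfig, condition: tuple[bool, bool],
                            phase: str, seed: int,
                            params: BoutParams | None = None):
    """Two participants' laughter bout tracks for one phase window.

    Returns (track_a, track_b): each a list of non-overlapping (onset_s,
    offset_s) tuples in absolute session time inside the extended phase window
    (task interval plus pre-onset).  Onsets follow a homogeneous Poisson
    process; durations are log-normal; offsets are clipped at the window end;
    overlapping bouts within a track are merged.
    """
    laughter, social = condition
    if params is None:
        params = bout_params_for(config, phase, laughter, social)
    for label, start, end, pre in phase_windows(config):
        if label == phase:
            w0, w1 = start - pre, end
            break
    else:
        raise KeyError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(seed)]))
    tracks = []
    for _p in (0, 1):
        n_bouts = rng.poisson(params.rate_per_s * (w1 - w0))
        onsets = np.sort(rng.uniform(w0, w1, size=n_bouts))
        mu_log = math.log(params.mean_duration_s) - params.sigma_log**2 / 2.0
        durs = rng.lognormal(mu_log, params.sigma_log, size=n_bouts)
        ivals = [(float(o), float(min(o + d, w1))) for o, d in zip(onsets, durs) if min(o + d, w1) > o]
        tracks.append(_merge(ivals))
    return tracks[0], tracks[1]


def _merge(intervals):
    """Union of possibly overlapping [on, off) intervals; touching merge."""
    out = []
    for on, off in sorted(intervals):
        if out and on <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], off))
        else:
            out.append((on, off))
    return out


OUTCOME_SCALES = {
    "liking": (4.0, 0.0, 8.0),        # (intercept, lo, hi) per dyad member scale x2 later
    "bonding": (3.0, 1.0, 7.0),
    "prosocial_money": (0.6, 0.0, 1.0),
    "prosocial_help": (0.8, 0.0, 1.0),
}


def generate_outcomes(sp: StructuralParams, treatment: np.ndarray,
                      mediator: np.ndarray | None = None, seed: int = 0,
                      scales: dict | None = None, clip: bool = True) -> pd.DataFrame:
    """Dyad-level outcome table from the linear structural model.

    mediator* = a * treatment + eps1 when not supplied; each outcome column is
    intercept + c' * treatment + b * mediator + eps2, clipped to its scale
    (clipping can be disabled for exact algebra checks).
    """
    treatment = np.asarray(treatment, dtype=float)
    rng = np.random.default_rng(seed)
    if mediator is None:
        mediator = sp.a_path * treatment + sp.sd_mediator_noise * rng.standard_normal(treatment.size)
    else:
        mediator = np.asarray(mediator, dtype=float)
        if mediator.size != treatment.size:
            raise ValueError("treatment and mediator must have the same length")
    scales = scales or OUTCOME_SCALES
    out = {"treatment": treatment, "mediator": mediator}
    for name, (icpt, lo, hi) in scales.items():
        y = icpt + sp.c_prime * treatment + sp.b_path * mediator \
            + sp.sd_outcome_noise * rng.standard_normal(treatment.size)
        out[name] = np.clip(y, lo, hi) if clip else y
    return pd.DataFrame(out)


@dataclass
class Cohort:
    """A full synthetic study: recordings, annotations, outcomes, ground truth."""

    config: SimulationConfig
    params: StructuralParams
    recordings: list[DyadRecording]
    annotations: pd.DataFrame   # dyad_id, participant, tier, onset_s, offset_s
    outcomes: pd.DataFrame      # one row per participant (questionnaire items)
    ground_truth: pd.DataFrame  # one row per dyad
    seed_manifest: dict = field(default_factory=dict)


def generate_cohort(config: SimulationConfig, sp: StructuralParams | None = None,
                    with_recordings: bool = True) -> Cohort:
    """Generate a balanced 2x2 cohort.

    Condition assignment is balanced (n_dyads_per_condition per cell); per-dyad
    seeds are spawned from the master seed by the documented splitting rule and
    recorded in the manifest.
    """
    sp = sp or StructuralParams()
    dyads = []
    for ci, (laughter, social) in enumerate(CONDITIONS):
        for k in range(config.n_dyads_per_condition):
            dyads.append((ci * config.n_dyads_per_condition + k, laughter, social))

    recordings, ann_rows, gt_rows = [], [], {}
    for dyad_id, laughter, social in dyads:
        kappa = config.kappa_for(laughter, social)
        if with_recordings:
            recordings.append(generate_dyad_timeseries(config, dyad_id, kappa, laughter, social))
        totals = {}
        for pi, (phase, _d, _p) in enumerate(config.phase_plan):
            ta, tb = generate_laughter_bouts(config, (laughter, social), phase,
                                             seed=dyad_id * 10 + pi)
            for part, track in ((0, ta), (1, tb)):
                for on, off in track:
                    ann_rows.append((dyad_id, part, "laughter", on, off))
            totals[phase] = sum(b - a for a, b in _merge(list(ta) + list(tb)))
        gt_rows[dyad_id] = {
            "dyad_id": dyad_id, "laughter": laughter, "social": social, "kappa": kappa,
            **{f"laughter_total_{ph}_s": t for ph, t in totals.items()},
        }

    treatment = np.array([float(l) for _, l, _s in dyads])
    rng_struct = config.rng(0, 999)
    mediator_true = sp.a_path * treatment
    mediator = mediator_true + sp.sd_mediator_noise * rng_struct.standard_normal(len(dyads))
    outcome_df = generate_outcomes(sp, treatment, mediator,
                                   seed=int(config.rng(0, 998).integers(2**31)))
    for i, (dyad_id, *_rest) in enumerate(dyads):
        gt_rows[dyad_id]["mediator_true"] = mediator_true[i]
        gt_rows[dyad_id]["mediator"] = mediator[i]
        for name in OUTCOME_SCALES:
            gt_rows[dyad_id][f"outcome_true_{name}"] = outcome_df[name].iloc[i]

    outcomes = _questionnaire_items(config, dyads, outcome_df)
    annotations = pd.DataFrame(ann_rows, columns=["dyad_id", "participant", "tier",
                                                  "onset_s", "offset_s"])
    gt = pd.DataFrame([gt_rows[d] for d, *_ in dyads])
    manifest = {"master_seed": config.seed,
                "splitting_rule": "SeedSequence([master_seed, dyad_index, stream_code])"}
    return Cohort(config, sp, recordings, annotations, outcomes, gt, manifest)


def _questionnaire_items(config, dyads, outcome_df) -> pd.DataFrame:
    """Per-participant questionnaire items consistent with the dyad-level outcomes."""
    rows = []
    for i, (dyad_id, laughter, social) in enumerate(dyads):
        rng = config.rng(dyad_id, 300)
        for part in (0, 1):
            l1 = np.clip(rng.normal(5.9, 1.0), 0, 8)
            l2 = np.clip(outcome_df["liking"].iloc[i] + rng.normal(0, 0.4), 0, 8)
            row = {"dyad_id": dyad_id, "participant": part,
                   "laughter": laughter, "social": social}
            for j in range(3):
                row[f"liking1_item{j + 1}"] = float(np.clip(l1 + rng.normal(0, 0.55), 0, 8))
                row[f"liking2_item{j + 1}"] = float(np.clip(l2 + rng.normal(0, 0.55), 0, 8))
            row["ios"] = int(np.clip(round(outcome_df["bonding"].iloc[i] + rng.normal(0, 0.8)), 1, 7))
            friend = float(np.clip(rng.normal(22, 4), 1, 30))
            ratio_m = float(np.clip(outcome_df["prosocial_money"].iloc[i] + rng.normal(0, 0.1), 0, 1))
            row["money_friend_eur"] = friend
            row["money_other_eur"] = float(np.clip(ratio_m * friend, 0, 30))
            row["help_general"] = int(rng.integers(3, 5))
            ratio_h = float(np.clip(outcome_df["prosocial_help"].iloc[i] + rng.normal(0, 0.1), 0, 1))
            row["help_other"] = int(np.clip(round(ratio_h * row["help_general"]), 1, 4))
            rows.append(row)
    return pd.DataFrame(rows)


def recording_to_intensity(recording: DyadRecording, phase: str, participant: int,
                           i0: float = 1.0, hbr_ratio: float = -0.25,
                           amplitude_molar: float = 1e-6):
    """Forward model: hemodynamic signal -> two-wavelength raw intensity.

    Treats the channel signal (arbitrary units) as delta-HbO with
    delta-HbR = hbr_ratio * delta-HbO, applies the modified Beer-Lambert law
    with the package's default extinction coefficients to obtain optical
    density, and returns intensities I = i0 * 10^(-OD).  Used to exercise the
    preprocessing chain end to end on synthetic data.
    """
    from .preprocess import DEFAULT_EXTINCTION, DEFAULT_DPF, DEFAULT_DISTANCE_CM, RawIntensity

    hbo = recording.phases[phase][participant] * amplitude_molar
    hbr = hbr_ratio * hbo
    conc = np.stack([hbo, hbr])  # (2, n_channels, n)
    ext = np.asarray(DEFAULT_EXTINCTION)
    intensities = []
    for w in range(2):
        od = (ext[w, 0] * conc[0] + ext[w, 1] * conc[1]) * DEFAULT_DISTANCE_CM * DEFAULT_DPF[w]
        intensities.append(i0 * 10.0 ** (-od))
    return RawIntensity(np.stack(intensities), recording.sampling_rate_hz)
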
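"""Synthetic bimodal EEG + fNIRS generator with known ground truth.

Emulates the three-condition action-observation study: continuous 64-channel
EEG (1 kHz) and 48-channel, three-wavelength fNIRS light intensities (27 ms
sampling) for a randomized 84-trial schedule.  Planted structure:

* a cue-locked negative deflection at observation onset (the visual evoked
  potential of the -500 ms cue) on posterior channels;
* a condition-ordered (Sd > Sm > Su) ERP component in the 350-400 ms window
  on a configurable set of responsive channels;
* condition-specific block-latent factors during the 0-3.5 s observation
  window, inducing condition-dependent inter-channel covariance (the basis
  of the brain-network classification).  EEG and fNIRS carry complementary
  partitions: EEG separates Sd from {Sm, Su}, fNIRS separates Su from
  {Sd, Sm};
* an HbO response peaking at 3 s post-onset with condition-ordered amplitude
  and hemispheric lateralization, plus a copy of the ERP waveform delayed by
  the neurovascular-coupling lag (default 1700 ms) so that the lagged
  EEG-HbO correlation surface peaks at the planted lag;
* physiological fNIRS noise (Mayer waves, cardiac pulsation, slow drift) and
  1/f EEG background with an alpha rhythm; EOG blinks leak into frontal EEG
  with fixed, exactly identifiable coefficients.

Concentrations are pushed through the forward Beer-Lambert model so the
recorded quantity is light intensity, as acquired by the instrument.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import layouts
from .paradigm import CONDITIONS, ParadigmConfig, TrialSchedule, build_schedule
from .preprocessing import (
    DEFAULT_DPF,
    DEFAULT_SEPARATION_CM,
    DEFAULT_WAVELENGTHS_NM,
    bandpass_filter,
    forward_intensity,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Signal-level knobs of the synthetic recordings.

    Amplitudes are in the units of the emulated quantity (uV for EEG,
    mM*mm for hemoglobin).  Noise levels are per-channel standard
    deviations unless noted.  ``noise_scale`` multiplies every stochastic
    component at once (0 gives noise-free recordings).
    """

    eeg_rate_hz: float = 1000.0
    fnirs_interval_s: float = 0.027
    wavelengths_nm: tuple[int, int, int] = DEFAULT_WAVELENGTHS_NM
    dpf: tuple[float, float, float] = DEFAULT_DPF
    separation_cm: float = DEFAULT_SEPARATION_CM
    i0: float = 1.0
    # EEG background
    eeg_pink_sigma_uv: float = 6.0
    eeg_pink_alpha: float = 1.0
    eeg_alpha_amp_uv: float = 3.0
    eeg_alpha_hz: float = 10.0
    eeg_white_sigma_uv: float = 1.0
    eeg_latent_sigma_uv: float = 4.0
    # Evoked shapes
    vep_amp_uv: float = -6.0
    vep_center_s: float = 0.05
    vep_sigma_s: float = 0.035
    # sharp early positive deflection of the cue-locked complex
    cue_p1_amp_uv: float = 0.0
    cue_p1_center_s: float = 0.012
    cue_p1_sigma_s: float = 0.008
    erp_sigma_s: float = 0.06
    n_responsive: int = 43
    # EOG
    eog_blink_rate_hz: float = 0.25
    eog_blink_amp_uv: float = 120.0
    eog_blink_sigma_s: float = 0.08
    # fNIRS
    hrf_undershoot: float = 0.4
    # neurovascular coupling gain: mM*mm of HbO per uV of the cross-channel
    # mean evoked waveform coupled into HbO at the planted lag
    nvc_coupling_gain: float = 0.0015
    fnirs_mayer_amp: float = 0.004
    fnirs_mayer_hz: float = 0.1
    fnirs_cardiac_amp: float = 0.002
    fnirs_cardiac_hz: float = 1.1
    fnirs_drift_sigma: float = 0.008
    fnirs_white_sigma: float = 0.002
    fnirs_latent_sigma: float = 0.006
    r_hb: float = -1.0 / 3.0
    noise_scale: float = 1.0

    @property
    def fnirs_rate_hz(self) -> float:
        return 1.0 / self.fnirs_interval_s


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted effects; condition keys follow the paradigm's names."""

    erp_amplitudes_by_condition: dict[str, float]
    hbo_peak_amp_by_condition: dict[str, float]
    lateralization_index_by_condition: dict[str, float]
    eeg_communities: dict[str, tuple[int, ...]]
    fnirs_communities: dict[str, tuple[int, ...]]
    erp_window_ms: tuple[float, float] = (350.0, 400.0)
    hbo_peak_time_s: float = 3.0
    nvc_lag_ms: float = 1700.0
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if self.nvc_lag_ms < 0:
            raise ValueError("nvc_lag_ms must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.effect_size > 0 and set(self.erp_amplitudes_by_condition) >= set(
            CONDITIONS
        ):
            a = self.erp_amplitudes_by_condition
            if not (a["Sd"] > a["Sm"] > a["Su"]):
                raise ValueError("ERP amplitudes must order Sd > Sm > Su")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _block_partition(n: int, n_blocks: int, shift: int = 0) -> tuple[int, ...]:
    """Assign channels to contiguous blocks, optionally rotated by ``shift``."""
    size = n // n_blocks
    return tuple(int(((i + shift) % n) // size) for i in range(n))


def default_ground_truth(
    effect_size: float = 1.0, nvc_lag_ms: float = 1700.0
) -> SyntheticGroundTruth:
    """Study-default planted effects.

    ERP window means are 12 +/- 8*effect_size uV (Sd/Sm/Su = 20/12/4 at
    the default effect size), HbO peaks 0.02 +/- 0.01*effect_size mM*mm, with
    left-lateralized Sd/Sm and right-lateralized Su.  EEG covariance blocks
    are identical for Sm and Su (so EEG resolves Sd against the rest) and
    fNIRS blocks are identical for Sd and Sm (fNIRS resolves Su): the two
    modalities are complementary and their fusion resolves all three.
    """
    e = float(effect_size)
    erp = {"Sd": 12 + 8 * e, "Sm": 12.0, "Su": 12 - 8 * e}
    hbo = {"Sd": 0.02 + 0.01 * e, "Sm": 0.02, "Su": 0.02 - 0.01 * e}
    lat = {"Sd": 0.4 * e, "Sm": 0.3 * e, "Su": -0.3 * e}
    eeg_comm = {
        "Sd": _block_partition(64, 4, shift=8),
        "Sm": _block_partition(64, 4, shift=0),
        "Su": _block_partition(64, 4, shift=0),
    }
    fnirs_comm = {
        "Sd": _block_partition(48, 4, shift=0),
        "Sm": _block_partition(48, 4, shift=0),
        "Su": _block_partition(48, 4, shift=6),
    }
    return SyntheticGroundTruth(
        erp_amplitudes_by_condition=erp,
        hbo_peak_amp_by_condition=hbo,
        lateralization_index_by_condition=lat,
        eeg_communities=eeg_comm,
        fnirs_communities=fnirs_comm,
        nvc_lag_ms=float(nvc_lag_ms),
        effect_size=e,
    )


def network_cohort_truth(
    effect_size: float = 1.0, nvc_lag_ms: float = 1700.0
) -> SyntheticGroundTruth:
    """Ground truth for classification cohorts: the planted effect is the
    condition-specific network structure.

    Evoked amplitude contrasts are kept small (though still ordered
    Sd > Sm > Su) so that inter-channel correlations are driven by the
    block-latent connectivity state rather than by evoked-amplitude
    differences; decoding then reflects the complementary network structure
    (EEG resolves Sd, fNIRS resolves Su) that the fusion is meant to exploit.
    """
    base = default_ground_truth(effect_size, nvc_lag_ms)
    e = float(effect_size)
    return SyntheticGroundTruth(
        erp_amplitudes_by_condition={
            "Sd": 12 + 1.0 * e, "Sm": 12.0, "Su": 12 - 1.0 * e
        },
        hbo_peak_amp_by_condition={
            "Sd": 0.02 + 0.002 * e, "Sm": 0.02, "Su": 0.02 - 0.002 * e
        },
        lateralization_index_by_condition=base.lateralization_index_by_condition,
        eeg_communities=base.eeg_communities,
        fnirs_communities=base.fnirs_communities,
        nvc_lag_ms=float(nvc_lag_ms),
        effect_size=e,
    )


@dataclass
class RawRecording:
    """One subject's continuous synthetic recordings plus ground truth."""

    eeg: np.ndarray  # (64, n_eeg) uV
    eog: np.ndarray  # (2, n_eeg) uV
    fnirs_intensity: np.ndarray  # (48, 3, n_fnirs) arbitrary units
    schedule: TrialSchedule
    ground_truth: SyntheticGroundTruth
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    eeg_channel_names: list[str] = field(default_factory=list)
    fnirs_channel_names: list[str] = field(default_factory=list)

    @property
    def eeg_rate_hz(self) -> float:
        return self.generator.eeg_rate_hz

    @property
    def fnirs_rate_hz(self) -> float:
        return self.generator.fnirs_rate_hz


def n_samples(duration_s: float, rate_hz: float) -> int:
    return int(math.ceil(round(duration_s * rate_hz, 9)))


def responsive_channels(config: GeneratorConfig | None = None) -> np.ndarray:
    """Indices of ERP-responsive EEG channels.

    Default: all channels except the most frontal ones in layout order,
    keeping ``n_responsive`` (43 of 64 by default).
    """
    cfg = config or GeneratorConfig()
    n_skip = 64 - cfg.n_responsive
    return np.arange(n_skip, 64)


def posterior_channels() -> np.ndarray:
    """Last 13 channels in layout order (parieto-occipital strip)."""
    return np.arange(51, 64)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_t: int, alpha: float,
                sigma: float) -> np.ndarray:
    """1/f^alpha noise, unit-variance shaped per channel then scaled."""
    out = np.empty((n_ch, n_t))
    freqs = np.fft.rfftfreq(n_t)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0
    for c in range(n_ch):
        spec = np.fft.rfft(rng.standard_normal(n_t))
        x = np.fft.irfft(spec * scale, n=n_t)
        sd = x.std()
        out[c] = x * (sigma / sd) if sd > 0 else x
    return out


def _gauss_pulse(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def erp_template(
    t_s: np.ndarray, condition: str, truth: SyntheticGroundTruth,
    config: GeneratorConfig,
) -> np.ndarray:
    """Deterministic evoked waveform (uV) at times ``t_s`` re observation onset.

    Negative cue-locked deflection at 0 plus the condition-scaled component
    centered in the ERP window.  This same template (delayed by the
    neurovascular lag) is the deterministic content coupled into HbO.
    """
    w0, w1 = truth.erp_window_ms
    center = (w0 + w1) / 2000.0
    vep = config.vep_amp_uv * _gauss_pulse(t_s, config.vep_center_s,
                                           config.vep_sigma_s)
    vep += config.cue_p1_amp_uv * _gauss_pulse(
        t_s, config.cue_p1_center_s, config.cue_p1_sigma_s
    )
    amp = truth.erp_amplitudes_by_condition[condition]
    bump = amp * _gauss_pulse(t_s, center, config.erp_sigma_s)
    return vep + bump


def generate_eeg(
    schedule: TrialSchedule,
    truth: SyntheticGroundTruth,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (eeg (64, n), eog (2, n)) continuous arrays in uV."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.eeg_rate_hz
    n_t = n_samples(schedule.total_duration_s, fs)
    ns = cfg.noise_scale

    eeg = _pink_noise(rng, 64, n_t, cfg.eeg_pink_alpha, cfg.eeg_pink_sigma_uv * ns)
    t_axis = np.arange(n_t) / fs
    if ns > 0:
        phases = rng.uniform(0, 2 * np.pi, 64)
        eeg += (cfg.eeg_alpha_amp_uv * ns) * np.sin(
            2 * np.pi * cfg.eeg_alpha_hz * t_axis[None, :] + phases[:, None]
        )
        eeg += rng.standard_normal((64, n_t)) * (cfg.eeg_white_sigma_uv * ns)

    resp = responsive_channels(cfg)
    post = posterior_channels()
    obs_n = n_samples(schedule.config.observation_s, fs)
    # evoked span: from -4 sigma of the VEP to the end of observation
    ev_start = -4 * cfg.vep_sigma_s
    ev_n = n_samples(schedule.config.observation_s - ev_start, fs)
    ev_t = ev_start + np.arange(ev_n) / fs
    vep_wave = _gauss_pulse(ev_t, cfg.vep_center_s, cfg.vep_sigma_s)
    p1_wave = _gauss_pulse(ev_t, cfg.cue_p1_center_s, cfg.cue_p1_sigma_s)
    w0, w1 = truth.erp_window_ms
    bump_wave = _gauss_pulse(ev_t, (w0 + w1) / 2000.0, cfg.erp_sigma_s)

    latent_sigma = cfg.eeg_latent_sigma_uv * truth.effect_size * ns
    for trial in schedule.trials:
        onset = int(round(trial.observation_onset_s * fs))
        s = onset + int(round(ev_start * fs))
        eeg[post, s : s + ev_n] += (
            cfg.vep_amp_uv * vep_wave + cfg.cue_p1_amp_uv * p1_wave
        )
        amp = truth.erp_amplitudes_by_condition[trial.condition]
        eeg[resp, s : s + ev_n] += amp * bump_wave
        if latent_sigma > 0:
            comm = np.asarray(truth.eeg_communities[trial.condition])
            blocks = np.unique(comm)
            z = rng.standard_normal((len(blocks), obs_n))
            # band-limit the latent factors to the EEG analysis band so the
            # planted covariance survives preprocessing
            z = bandpass_filter(z, fs, 1.0, 30.0)
            z *= latent_sigma / np.maximum(z.std(axis=1, keepdims=True), 1e-12)
            # zero-sum across blocks: the latent state cancels from the
            # cross-channel mean, so summary waveforms stay clean while the
            # block covariance structure is preserved
            z -= z.mean(axis=0, keepdims=True)
            eeg[:, onset : onset + obs_n] += z[comm]

    # EOG with blink transients; fixed leakage into the (frontal) channels
    eog = rng.standard_normal((2, n_t)) * (3.0 * ns)
    if ns > 0:
        for ch in range(2):
            n_blinks = rng.poisson(cfg.eog_blink_rate_hz * schedule.total_duration_s)
            centers = rng.uniform(0, schedule.total_duration_s, n_blinks)
            for c in centers:
                i0 = int(round((c - 4 * cfg.eog_blink_sigma_s) * fs))
                i1 = int(round((c + 4 * cfg.eog_blink_sigma_s) * fs))
                i0, i1 = max(i0, 0), min(i1, n_t)
                tt = np.arange(i0, i1) / fs
                eog[ch, i0:i1] += cfg.eog_blink_amp_uv * _gauss_pulse(
                    tt, c, cfg.eog_blink_sigma_s
                )
    eeg += eog_leakage_matrix() @ eog
    return eeg, eog


def eog_leakage_matrix() -> np.ndarray:
    """Fixed (64, 2) EOG-to-EEG mixing, decaying from frontal to posterior."""
    idx = np.arange(64)
    b = np.stack(
        [0.35 * np.exp(-idx / 8.0), 0.20 * np.exp(-idx / 12.0)], axis=1
    )
    return b


def calibrated_hrf(
    target_peak_s: float, box_duration_s: float, dt: float,
    undershoot: float = 0.1,
) -> np.ndarray:
    """Boxcar (x) double-gamma response whose maximum sits at ``target_peak_s``.

    The double-gamma time-to-peak is found by bisection so that the
    convolution of the observation boxcar with the kernel peaks at the
    requested time.  Returned waveform is unit peak amplitude, sampled at
    ``dt`` from 0, long enough to contain the undershoot.
    """
    if target_peak_s <= dt:
        raise ValueError("target peak must exceed one sample")
    span = box_duration_s + 16.0
    t = np.arange(0.0, span, dt)
    box_n = max(int(round(box_duration_s / dt)), 1)

    def response(tp: float) -> np.ndarray:
        # high shape parameter: delayed, sigmoid-like onset so the early
        # post-lag window stays dominated by the fast coupled component
        a1 = 10.0
        b1 = tp / (a1 - 1)
        a2, b2 = 20.0, tp / (a1 - 1)
        g1 = (t / b1) ** (a1 - 1) * np.exp(-t / b1)
        g2 = (t / b2) ** (a2 - 1) * np.exp(-t / b2)
        h = g1 / g1.max() - undershoot * g2 / g2.max()
        r = np.convolve(h, np.ones(box_n))[: len(t)]
        return r

    def peak_time(tp: float) -> float:
        return float(np.argmax(response(tp))) * dt

    lo, hi = dt, target_peak_s
    if peak_time(hi) < target_peak_s:
        # boxcar integration alone can push the peak late; shrink until it
        # brackets, otherwise accept the closest achievable kernel
        while peak_time(lo) > target_peak_s and lo > 1e-3:
            lo /= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if peak_time(mid) < target_peak_s:
            lo = mid
        else:
            hi = mid
    r = response(0.5 * (lo + hi))
    r /= np.abs(r).max()
    # trim the tail once the undershoot has decayed
    nz = np.nonzero(np.abs(r) > 1e-4)[0]
    return r[: int(nz[-1]) + 1] if len(nz) else r


def generate_fnirs(
    schedule: TrialSchedule,
    truth: SyntheticGroundTruth,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Return (48, 3, n) light intensities from the forward optical model."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.fnirs_rate_hz
    dt = cfg.fnirs_interval_s
    n_t = n_samples(schedule.total_duration_s, fs)
    ns = cfg.noise_scale

    hbo = np.zeros((48, n_t))
    lag_s = truth.nvc_lag_ms / 1000.0
    hrf_peak_after_lag = truth.hbo_peak_time_s - lag_s
    if hrf_peak_after_lag <= dt:
        raise ValueError(
            f"nvc_lag_ms={truth.nvc_lag_ms} leaves no room before the HbO "
            f"peak at {truth.hbo_peak_time_s} s"
        )
    hrf = calibrated_hrf(
        hrf_peak_after_lag, schedule.config.observation_s, dt, cfg.hrf_undershoot
    )
    lag_n = int(round(lag_s * fs))

    # Deterministic ERP copies, resampled to the fNIRS grid, per condition.
    # The coupled waveform mirrors the cross-channel mean of the evoked EEG
    # (cue-locked complex on the posterior strip, condition component on the
    # responsive set), so the lagged correlation with the measured summary
    # ERP peaks at the planted lag.
    erp_span_t = np.arange(0.0, 0.7, dt)
    w0, w1 = truth.erp_window_ms
    post_frac = len(posterior_channels()) / 64.0
    bump_frac = cfg.n_responsive / 64.0
    cue_complex = post_frac * (
        cfg.vep_amp_uv
        * _gauss_pulse(erp_span_t, cfg.vep_center_s, cfg.vep_sigma_s)
        + cfg.cue_p1_amp_uv
        * _gauss_pulse(erp_span_t, cfg.cue_p1_center_s, cfg.cue_p1_sigma_s)
    )
    bump_part = _gauss_pulse(erp_span_t, (w0 + w1) / 2000.0, cfg.erp_sigma_s)
    erp_copy = {
        c: cfg.nvc_coupling_gain * (
            cue_complex
            + bump_frac * truth.erp_amplitudes_by_condition[c] * bump_part
        )
        for c in schedule.config.condition_names
        if c in truth.erp_amplitudes_by_condition
    }

    left = np.arange(24)
    side_gain = np.ones(48)
    # the latent connectivity state spans the whole trial slot, not just the
    # observation window, so trial-mean variance is uniform across the epoch
    lat_pre_n = n_samples(
        schedule.config.pre_rest_s + schedule.config.cue_s, fs
    )
    lat_n = n_samples(schedule.config.trial_duration_s, fs)
    latent_sigma = cfg.fnirs_latent_sigma * truth.effect_size * ns
    smooth_n = max(int(round(0.15 / dt)), 1)

    for trial in schedule.trials:
        onset = int(round(trial.observation_onset_s * fs))
        cond = trial.condition
        li = truth.lateralization_index_by_condition.get(cond, 0.0)
        side_gain[:] = 1.0 - li / 2.0
        side_gain[left] = 1.0 + li / 2.0

        amp = truth.hbo_peak_amp_by_condition[cond]
        s = onset + lag_n
        seg = hrf[: max(0, min(len(hrf), n_t - s))]
        hbo[:, s : s + len(seg)] += amp * side_gain[:, None] * seg[None, :]

        if cond in erp_copy:
            ec = erp_copy[cond]
            seg2 = ec[: max(0, min(len(ec), n_t - s))]
            hbo[:, s : s + len(seg2)] += side_gain[:, None] * seg2[None, :]

        if latent_sigma > 0:
            comm = np.asarray(truth.fnirs_communities[cond])
            blocks = np.unique(comm)
            z = rng.standard_normal((len(blocks), lat_n + 2 * smooth_n))
            kern = np.hanning(2 * smooth_n + 1)
            kern /= kern.sum()
            z = np.apply_along_axis(np.convolve, 1, z, kern, "same")
            z = z[:, smooth_n : smooth_n + lat_n]
            z *= latent_sigma / np.maximum(z.std(axis=1, keepdims=True), 1e-12)
            z -= z.mean(axis=0, keepdims=True)  # cancels from channel mean
            i0_seg = max(onset - lat_pre_n, 0)
            seg3 = z[comm][:, : n_t - i0_seg]
            hbo[:, i0_seg : i0_seg + seg3.shape[1]] += seg3

    if ns > 0:
        t_axis = np.arange(n_t) / fs
        ph_m = rng.uniform(0, 2 * np.pi, 48)
        ph_c = rng.uniform(0, 2 * np.pi, 48)
        hbo += (cfg.fnirs_mayer_amp * ns) * np.sin(
            2 * np.pi * cfg.fnirs_mayer_hz * t_axis[None, :] + ph_m[:, None]
        )
        hbo += (cfg.fnirs_cardiac_amp * ns) * np.sin(
            2 * np.pi * cfg.fnirs_cardiac_hz * t_axis[None, :] + ph_c[:, None]
        )
        drift = np.cumsum(rng.standard_normal((48, n_t)), axis=1)
        drift -= drift.mean(axis=1, keepdims=True)
        drift *= (cfg.fnirs_drift_sigma * ns) / np.maximum(
            drift.std(axis=1, keepdims=True), 1e-12
        )
        hbo += drift
        hbo += rng.standard_normal((48, n_t)) * (cfg.fnirs_white_sigma * ns)

    hbr = cfg.r_hb * hbo
    return forward_intensity(hbo, hbr, cfg.wavelengths_nm, cfg.dpf, cfg.i0)


def generate_subject(
    paradigm: ParadigmConfig | None = None,
    truth: SyntheticGroundTruth | None = None,
    generator: GeneratorConfig | None = None,
    seed: int = 0,
) -> RawRecording:
    """Compose schedule + EEG + fNIRS into one subject's recording."""
    paradigm = paradigm or ParadigmConfig()
    if truth is None:
        truth = default_ground_truth()
    generator = generator or GeneratorConfig()
    schedule = build_schedule(paradigm)
    ss = np.random.SeedSequence(seed).spawn(2)
    eeg_seed = int(ss[0].generate_state(1)[0] % (2**31))
    fnirs_seed = int(ss[1].generate_state(1)[0] % (2**31))
    eeg, eog = generate_eeg(schedule, truth, generator, eeg_seed)
    intensity = generate_fnirs(schedule, truth, generator, fnirs_seed)
    eeg_names, _ = layouts.standard_64_layout()
    f_names, _ = layouts.fnirs_parietal_layout()
    return RawRecording(
        eeg=eeg,
        eog=eog,
        fnirs_intensity=intensity,
        schedule=schedule,
        ground_truth=truth,
        generator=generator,
        eeg_channel_names=eeg_names,
        fnirs_channel_names=f_names,
    )
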
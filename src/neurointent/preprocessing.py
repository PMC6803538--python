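"""Signal conditioning: filters, EOG regression, MBLL conversion, epoching.

EEG is notch- and band-pass filtered (1-30 Hz analysis band), ocular
artifacts are removed by least-squares regression on the EOG channels, and
trials are cut relative to observation onset and baseline-corrected on
(-700, -500) ms.  fNIRS light intensities are converted to hemoglobin
concentration changes with the modified Beer-Lambert law (MBLL), band-pass
filtered, epoched, and baseline-corrected on (-6.5, -0.5) s.

All filters are zero-phase (forward-backward second-order sections), so the
latency of the 350-400 ms component of interest is not distorted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .paradigm import ConfigurationError, TrialSchedule

# --------------------------------------------------------------------------
# Optical constants
#
# Hemoglobin extinction coefficients in 1/(mM*cm) at the instrument's three
# wavelengths, from the standard compiled in-vitro spectra (Cope's
# tabulation, as shipped with common NIRS toolboxes), and adult-head
# differential pathlength factors.  Both are documented defaults; callers
# may override.
EXTINCTION_MM_CM: dict[int, tuple[float, float]] = {
    # wavelength nm: (eps_HbO, eps_HbR)
    780: (0.7360, 1.1050),
    805: (0.8563, 0.7958),
    830: (0.9745, 0.6931),
}
DEFAULT_WAVELENGTHS_NM = (780, 805, 830)
DEFAULT_DPF = (6.3, 6.0, 5.75)
DEFAULT_SEPARATION_CM = 3.0


class FilterError(ValueError):
    """Raised when a filter specification is invalid for the sampling rate."""


class EpochError(ValueError):
    """Raised when epoch windows fall outside the available data."""


class MBLLError(ValueError):
    """Raised for invalid light-intensity input to the MBLL conversion."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass or notch filter specification.

    ``order`` is the Butterworth order of the underlying one-pass design;
    zero-phase application doubles the effective order, giving monotone
    (ripple-free) passbands and >=20 dB attenuation one octave outside the
    band at the default order.
    """

    kind: str = "bandpass"  # "bandpass" | "notch"
    low_hz: float | None = 1.0
    high_hz: float | None = 30.0
    order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0

    def validate(self, rate_hz: float) -> None:
        nyq = rate_hz / 2.0
        if self.kind == "bandpass":
            low, high = self.low_hz, self.high_hz
            if low is not None and high is not None and not (0 < low < high < nyq):
                raise FilterError(
                    f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz"
                )
            if low is None and high is None:
                raise FilterError("bandpass needs at least one band edge")
            for edge in (low, high):
                if edge is not None and not (0 < edge < nyq):
                    raise FilterError(f"edge {edge} Hz outside (0, {nyq}) Hz")
        elif self.kind == "notch":
            if not (0 < self.notch_hz < nyq):
                raise FilterError(f"notch {self.notch_hz} Hz outside (0, {nyq}) Hz")
        else:
            raise FilterError(f"unknown filter kind {self.kind!r}")


def bandpass_filter(
    x: np.ndarray,
    rate_hz: float,
    low_hz: float | None = 1.0,
    high_hz: float | None = 30.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filter along the last axis.

    Passing ``low_hz=None`` gives a low-pass, ``high_hz=None`` a high-pass.
    """
    spec = FilterSpec("bandpass", low_hz, high_hz, order)
    spec.validate(rate_hz)
    nyq = rate_hz / 2.0
    if low_hz is None:
        sos = sps.butter(order, high_hz / nyq, btype="lowpass", output="sos")
    elif high_hz is None:
        sos = sps.butter(order, low_hz / nyq, btype="highpass", output="sos")
    else:
        sos = sps.butter(
            order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos"
        )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def notch_filter(
    x: np.ndarray, rate_hz: float, notch_hz: float = 50.0, q: float = 30.0
) -> np.ndarray:
    """Zero-phase IIR notch at ``notch_hz`` along the last axis."""
    spec = FilterSpec("notch", notch_hz=notch_hz, notch_q=q)
    spec.validate(rate_hz)
    b, a = sps.iirnotch(notch_hz, q, fs=rate_hz)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def apply_filter(x: np.ndarray, rate_hz: float, spec: FilterSpec) -> np.ndarray:
    if spec.kind == "bandpass":
        return bandpass_filter(x, rate_hz, spec.low_hz, spec.high_hz, spec.order)
    return notch_filter(x, rate_hz, spec.notch_hz, spec.notch_q)


def remove_eog(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Subtract the least-squares projection of each EEG channel onto the EOG.

    ``eeg`` is (channels, time), ``eog`` is (n_eog, time), synchronized.
    Constant (zero-variance) EOG channels carry no artifact information and
    are skipped with a warning.
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eeg.shape[-1] != eog.shape[-1]:
        raise ValueError("EEG and EOG must share the time axis")
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    keep = eog_c.std(axis=1) > 0
    if not np.all(keep):
        warnings.warn(
            f"skipping constant EOG channel(s) {np.where(~keep)[0].tolist()}",
            stacklevel=2,
        )
    eog_c = eog_c[keep]
    if eog_c.shape[0] == 0:
        return eeg.copy()
    # beta fit on centered data (no intercept bias), applied to the raw EOG:
    # an input of the exact form clean + B @ eog is then mapped to
    # clean - proj(clean), identical to what the clean signal alone gives
    eeg_c = eeg - eeg.mean(axis=1, keepdims=True)
    beta, *_ = np.linalg.lstsq(eog_c.T, eeg_c.T, rcond=None)
    return eeg - beta.T @ eog[keep]


# --------------------------------------------------------------------------
# Modified Beer-Lambert law


def _extinction_matrix(wavelengths_nm) -> np.ndarray:
    rows = []
    for wl in wavelengths_nm:
        if int(wl) not in EXTINCTION_MM_CM:
            raise MBLLError(f"no extinction coefficients for {wl} nm")
        rows.append(EXTINCTION_MM_CM[int(wl)])
    return np.asarray(rows, dtype=float)  # (n_wl, 2)


def forward_intensity(
    hbo: np.ndarray,
    hbr: np.ndarray,
    wavelengths_nm=DEFAULT_WAVELENGTHS_NM,
    dpf=DEFAULT_DPF,
    i0: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations (mM*mm) -> light intensity.

    ``hbo``/``hbr`` are (channels, time) pathlength-scaled concentration
    changes in mM*mm.  Returns (channels, n_wavelengths, time) intensities
    I = i0 * 10**(-dOD); intensities are strictly positive by construction.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    eps = _extinction_matrix(wavelengths_nm)
    dpf = np.asarray(dpf, dtype=float)
    # mM*mm -> mM*cm, then dOD(wl) = dpf(wl) * (eps @ [c_o, c_r])
    conc_cm = np.stack([hbo, hbr], axis=0) / 10.0  # (2, ch, t)
    dod = np.einsum("wk,kct->cwt", eps, conc_cm) * dpf[None, :, None]
    return np.asarray(i0) * np.power(10.0, -dod)


def mbll_convert(
    intensity: np.ndarray,
    wavelengths_nm=DEFAULT_WAVELENGTHS_NM,
    dpf=DEFAULT_DPF,
    i_ref: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MBLL: light intensities -> (dHbO, dHbR, dHbT) in mM*mm.

    ``intensity`` is (channels, n_wavelengths, time), strictly positive.
    dOD(wl, t) = -log10(I(t) / I_ref(wl)); the per-timepoint 3x2 linear
    system dOD/DPF = eps @ [dHbO, dHbR] (concentrations carrying the
    effective pathlength, mM*cm) is solved by least squares and reported in
    mM*mm.  ``i_ref`` defaults to the per-channel, per-wavelength time mean;
    the reference choice only shifts each channel by a constant, which the
    epoch baseline correction removes.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 3:
        raise MBLLError("intensity must be (channels, wavelengths, time)")
    bad = intensity <= 0
    if np.any(bad):
        ch, wl, t = (int(v[0]) for v in np.nonzero(bad))
        raise MBLLError(
            f"non-positive intensity at channel {ch}, wavelength index {wl}, "
            f"sample {t}"
        )
    if i_ref is None:
        i_ref = intensity.mean(axis=2)
    i_ref = np.asarray(i_ref, dtype=float)
    dod = -np.log10(intensity / i_ref[:, :, None])  # (ch, wl, t)
    eps = _extinction_matrix(wavelengths_nm)
    dpf = np.asarray(dpf, dtype=float)
    dod_adj = dod / dpf[None, :, None]
    pinv = np.linalg.pinv(eps)  # (2, n_wl)
    conc_cm = np.einsum("kw,cwt->kct", pinv, dod_adj)
    hbo, hbr = conc_cm[0] * 10.0, conc_cm[1] * 10.0
    return hbo, hbr, hbo + hbr


# --------------------------------------------------------------------------
# Epoching


def n_epoch_samples(window_s: tuple[float, float], rate_hz: float) -> int:
    """Number of samples in an epoch window: ceil(duration * rate)."""
    return int(math.ceil(round((window_s[1] - window_s[0]) * rate_hz, 9)))


@dataclass
class EpochSet:
    """Trials x channels x time array with labels and timing metadata.

    ``window_s`` is (start, stop) relative to observation onset; time point
    ``i`` sits at ``window_s[0] + i / rate_hz``.
    """

    data: np.ndarray
    rate_hz: float
    labels: np.ndarray
    modality: str
    window_s: tuple[float, float]
    baseline_window_s: tuple[float, float] | None = None
    channel_names: list[str] | None = None
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.data.shape[2]) / self.rate_hz

    @property
    def t0_offset_s(self) -> float:
        """Time of observation onset measured from the epoch start."""
        return -self.window_s[0]

    def time_mask(self, start_s: float, stop_s: float) -> np.ndarray:
        t = self.times_s
        return (t >= start_s - 1e-12) & (t <= stop_s + 1e-12)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(str(lab))
        return sorted(seen)


def epoch_extract(
    continuous: np.ndarray,
    rate_hz: float,
    schedule: TrialSchedule,
    window_s: tuple[float, float],
    modality: str = "EEG",
    baseline_window_s: tuple[float, float] | None = None,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Cut one epoch per scheduled trial, aligned to observation onset."""
    continuous = np.asarray(continuous, dtype=float)
    n_time = continuous.shape[-1]
    n_samp = n_epoch_samples(window_s, rate_hz)
    starts = np.array(
        [int(round((t.observation_onset_s + window_s[0]) * rate_hz)) for t in schedule.trials]
    )
    bad = [
        t.index
        for t, s in zip(schedule.trials, starts)
        if s < 0 or s + n_samp > n_time
    ]
    if bad:
        raise EpochError(f"epoch window out of bounds for trial indices {bad}")
    data = np.stack([continuous[:, s : s + n_samp] for s in starts], axis=0) if len(
        starts
    ) else np.empty((0, continuous.shape[0], n_samp))
    return EpochSet(
        data=data,
        rate_hz=rate_hz,
        labels=schedule.conditions,
        modality=modality,
        window_s=window_s,
        baseline_window_s=baseline_window_s,
        channel_names=channel_names,
        colors=np.array([t.color for t in schedule.trials]),
    )


def baseline_correct(
    epochs: EpochSet, baseline_window_s: tuple[float, float] | None = None
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    win = baseline_window_s or epochs.baseline_window_s
    if win is None:
        raise ConfigurationError("no baseline window given")
    t = epochs.times_s
    if win[0] < t[0] - 1e-9 or win[1] > t[-1] + 1e-9:
        raise EpochError(f"baseline window {win} outside epoch {epochs.window_s}")
    mask = epochs.time_mask(*win)
    if not mask.any():
        raise EpochError(f"baseline window {win} contains no samples")
    corrected = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=corrected, baseline_window_s=win)


# --------------------------------------------------------------------------
# Modality pipelines

DEFAULT_EEG_WINDOW_S = (-0.7, 3.5)
DEFAULT_EEG_BASELINE_S = (-0.7, -0.5)
DEFAULT_FNIRS_WINDOW_S = (-6.5, 5.5)
DEFAULT_FNIRS_BASELINE_S = (-6.5, -0.5)


@dataclass(frozen=True)
class PreprocessingConfig:
    """End-to-end preprocessing parameters for both modalities.

    ``fnirs_band_hz`` is the sensor-statistics band; the network and
    neurovascular-coupling stages override it (see their configs) because a
    3.5 s analysis window holds less than half a cycle at 0.1 Hz.
    """

    eeg_band_hz: tuple[float, float] = (1.0, 30.0)
    eeg_notch_hz: float = 50.0
    eeg_window_s: tuple[float, float] = DEFAULT_EEG_WINDOW_S
    eeg_baseline_s: tuple[float, float] = DEFAULT_EEG_BASELINE_S
    fnirs_band_hz: tuple[float | None, float | None] = (0.01, 0.1)
    fnirs_window_s: tuple[float, float] = DEFAULT_FNIRS_WINDOW_S
    fnirs_baseline_s: tuple[float, float] = DEFAULT_FNIRS_BASELINE_S
    filter_order: int = 4
    remove_eog: bool = True


def preprocess_eeg(
    eeg: np.ndarray,
    eog: np.ndarray | None,
    rate_hz: float,
    schedule: TrialSchedule,
    config: PreprocessingConfig | None = None,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Notch -> band-pass -> EOG regression -> epoch -> baseline-correct."""
    cfg = config or PreprocessingConfig()
    x = np.asarray(eeg, dtype=float)
    if cfg.eeg_notch_hz and cfg.eeg_notch_hz < rate_hz / 2:
        x = notch_filter(x, rate_hz, cfg.eeg_notch_hz)
    x = bandpass_filter(x, rate_hz, *cfg.eeg_band_hz, order=cfg.filter_order)
    if cfg.remove_eog and eog is not None:
        eog_f = bandpass_filter(
            np.asarray(eog, dtype=float), rate_hz, *cfg.eeg_band_hz,
            order=cfg.filter_order,
        )
        x = remove_eog(x, eog_f)
    epochs = epoch_extract(
        x, rate_hz, schedule, cfg.eeg_window_s, "EEG", cfg.eeg_baseline_s,
        channel_names,
    )
    return baseline_correct(epochs)


def preprocess_fnirs(
    intensity: np.ndarray,
    rate_hz: float,
    schedule: TrialSchedule,
    config: PreprocessingConfig | None = None,
    wavelengths_nm=DEFAULT_WAVELENGTHS_NM,
    dpf=DEFAULT_DPF,
    band_hz: tuple[float | None, float | None] | None = None,
    i_ref: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> dict[str, EpochSet]:
    """MBLL -> band-pass -> epoch -> baseline-correct; returns HbO/HbR/HbT."""
    cfg = config or PreprocessingConfig()
    band = band_hz if band_hz is not None else cfg.fnirs_band_hz
    hbo, hbr, hbt = mbll_convert(intensity, wavelengths_nm, dpf, i_ref=i_ref)
    out: dict[str, EpochSet] = {}
    for name, series in (("HbO", hbo), ("HbR", hbr), ("HbT", hbt)):
        x = series
        if band is not None and (band[0] is not None or band[1] is not None):
            x = bandpass_filter(x, rate_hz, band[0], band[1], order=cfg.filter_order)
        epochs = epoch_extract(
            x, rate_hz, schedule, cfg.fnirs_window_s, name, cfg.fnirs_baseline_s,
            channel_names,
        )
        out[name] = baseline_correct(epochs)
    return out
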
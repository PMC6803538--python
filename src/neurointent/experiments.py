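"""Reproducible validation experiments on synthetic cohorts.

Each function regenerates its inputs from a seed, runs the pipeline stages it
exercises, and returns summary numbers.  Problem sizes default to what a
single CPU core handles in minutes: the neurovascular-lag sweep uses the full
84-trial paradigm with EEG generated at 250 Hz (the lag analysis itself
interpolates to the 1 ms grid, so the generator rate only sets synthesis
cost), and classification cohorts use a reduced SVM grid with 2 repetitions
of stratified 10-fold cross-validation per modality.
"""

from __future__ import annotations

import warnings

import numpy as np

from .classify import IntentionDecoder, fuse, repeated_cv
from .network import feature_table
from .nvc import high_corr_region, lag_surface, summary_waveform
from .paradigm import ParadigmConfig
from .preprocessing import (
    forward_intensity,
    mbll_convert,
    preprocess_eeg,
    preprocess_fnirs,
)
from .sensor_stats import channel_anova, grand_average, hbo_block_ttest
from .synth import (
    GeneratorConfig,
    default_ground_truth,
    generate_subject,
    network_cohort_truth,
)

FAST_GENERATOR = GeneratorConfig(eeg_rate_hz=250.0)
REDUCED_C_GRID = (2.0**-1, 2.0**3, 2.0**7)
REDUCED_GAMMA_GRID = (2.0**-9, 2.0**-5, 2.0**-1)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def lag_recovery_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    planted_lag_ms: float = 1700.0,
    tolerance_ms: float = 54.0,
    threshold: float = 0.8,
) -> dict:
    """Recover the planted neurovascular lag from fresh subjects.

    Returns the hit rate (|recovered - planted| <= tolerance), the recovered
    lags, window lengths, and peak correlations.
    """
    para = ParadigmConfig()
    truth = default_ground_truth(nvc_lag_ms=planted_lag_ms)
    lags, xs, rs = [], [], []
    for s in _spawn_seeds(seed, n_seeds):
        rec = generate_subject(para, truth, FAST_GENERATOR, seed=s)
        eeg_ep = preprocess_eeg(rec.eeg, rec.eog, rec.eeg_rate_hz, rec.schedule)
        hbo_ep = preprocess_fnirs(
            rec.fnirs_intensity, rec.fnirs_rate_hz, rec.schedule,
            band_hz=(0.01, None),
        )["HbO"]
        conds, ga_e = grand_average(eeg_ep)
        _, ga_h = grand_average(hbo_ep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surface = lag_surface(
                summary_waveform(ga_e), eeg_ep.times_s,
                summary_waveform(ga_h), hbo_ep.times_s, conds,
            )
            region = high_corr_region(surface, threshold)
        lags.append(region.peak_y_ms)
        xs.append(region.peak_x_ms)
        rs.append(region.peak_r)
    lags_arr = np.array(lags, dtype=float)
    hits = np.abs(lags_arr - planted_lag_ms) <= tolerance_ms
    return {
        "planted_lag_ms": planted_lag_ms,
        "recovered_lags_ms": lags,
        "peak_window_ms": xs,
        "peak_r": rs,
        "hit_rate": float(hits.mean()),
        "median_lag_ms": float(np.median(lags_arr)),
        "n_seeds": n_seeds,
    }


def _subject_features(seed: int):
    para = ParadigmConfig()
    truth = network_cohort_truth()
    rec = generate_subject(para, truth, FAST_GENERATOR, seed=seed)
    eeg_ep = preprocess_eeg(rec.eeg, rec.eog, rec.eeg_rate_hz, rec.schedule)
    hbo_ep = preprocess_fnirs(
        rec.fnirs_intensity, rec.fnirs_rate_hz, rec.schedule,
        band_hz=(0.01, 2.0),
    )["HbO"]
    return feature_table(eeg_ep), feature_table(hbo_ep)


def _reduced_decoder(seed: int = 0) -> IntentionDecoder:
    return IntentionDecoder(
        n_keep=60, k_neighbors=10, c_grid=REDUCED_C_GRID,
        gamma_grid=REDUCED_GAMMA_GRID, inner_folds=3, seed=seed,
    )


def classification_cohort(
    n_subjects: int = 10, seed: int = 0, n_reps: int = 2, n_folds: int = 10
) -> dict:
    """Decode intention per modality on a cohort of simulated subjects.

    EEG and fNIRS carry complementary planted network structure; reports
    per-subject accuracies for EEG, fNIRS and the fused feature set.
    """
    accs: dict[str, list[float]] = {"eeg": [], "fnirs": [], "fused": []}
    for s in _spawn_seeds(seed, n_subjects):
        ef, ff = _subject_features(s)
        tables = {"eeg": ef, "fnirs": ff, "fused": fuse(ef, ff)}
        for name, table in tables.items():
            res = repeated_cv(
                table.values, table.labels, n_reps=n_reps, n_folds=n_folds,
                decoder=_reduced_decoder(s), seed=s,
            )
            accs[name].append(res.mean_accuracy)
    fused_wins = [
        f > max(e, n) and f > 0.45
        for e, n, f in zip(accs["eeg"], accs["fnirs"], accs["fused"])
    ]
    return {
        "accuracies": accs,
        "mean_accuracy_pct": {
            k: float(100 * np.mean(v)) for k, v in accs.items()
        },
        "fused_wins": int(np.sum(fused_wins)),
        "n_subjects": n_subjects,
    }


def null_classification(
    seed: int = 0, n_reps: int = 10, n_folds: int = 10
) -> dict:
    """Permuted-label cross-validated accuracy on one subject's features."""
    seeds = _spawn_seeds(seed, 2)
    ef, ff = _subject_features(seeds[0])
    table = fuse(ef, ff)
    rng = np.random.default_rng(seeds[1])
    permuted = rng.permutation(table.labels)
    res = repeated_cv(
        table.values, permuted, n_reps=n_reps, n_folds=n_folds,
        decoder=_reduced_decoder(seeds[1]), seed=seeds[1],
    )
    n_pred = len(permuted) * n_reps
    half_width = 1.96 * np.sqrt((1 / 3) * (2 / 3) / n_pred)
    return {
        "accuracy_pct": 100 * res.mean_accuracy,
        "ci_half_width_pct": 100 * half_width,
        "within_ci": bool(abs(res.mean_accuracy - 1 / 3) <= half_width),
        "n_predictions": n_pred,
    }


def type_one_error_rates(
    n_channels: int = 500, n_trials: int = 30, seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rates of the channel ANOVA and HbO block t-test under null
    synthesis (iid noise epochs, balanced random labels)."""
    from .preprocessing import EpochSet

    rng = np.random.default_rng(seed)
    labels = np.array(["Sd", "Sm", "Su"] * (n_trials // 3))
    anova_ep = EpochSet(
        data=rng.standard_normal((len(labels), n_channels, 40)),
        rate_hz=50.0, labels=labels, modality="EEG",
        window_s=(-0.2, 0.6), baseline_window_s=(-0.2, -0.1),
    )
    res = channel_anova(anova_ep, (0.0, 0.5), alpha=alpha)
    anova_rate = float(res.significant.mean())

    fs = 1000 / 27
    hbo_ep = EpochSet(
        data=rng.standard_normal((len(labels), n_channels, 445)),
        rate_hz=fs, labels=labels, modality="HbO",
        window_s=(-6.5, 5.5), baseline_window_s=(-6.5, -0.5),
    )
    tres = hbo_block_ttest(hbo_ep, times_s=(3.0,), alpha=alpha)
    ttest_rate = float(tres[3.0].significant.mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_channels))
    return {
        "alpha": alpha,
        "anova_rate": anova_rate,
        "ttest_rate": ttest_rate,
        "se": se,
        "n_channels": n_channels,
    }


def relieff_planted_feature_rate(
    n_seeds: int = 100, seed: int = 0, n_noise: int = 50
) -> dict:
    """Fraction of seeds where a perfectly separating feature outranks
    ``n_noise`` pure-noise features."""
    from .classify import ReliefF

    wins = 0
    for s in _spawn_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        y = np.repeat(["Sd", "Sm", "Su"], 20)
        X = rng.standard_normal((60, n_noise + 1))
        X[:, 0] = np.select(
            [y == "Sd", y == "Sm", y == "Su"], [0.0, 1.0, 2.0]
        ) + 0.05 * rng.standard_normal(60)
        rf = ReliefF(n_keep=5, k_neighbors=10).fit(X, y)
        wins += int(rf.ranking_[0] == 0)
    return {"top1_rate": wins / n_seeds, "n_seeds": n_seeds}


def mbll_roundtrip_error(seed: int = 0, n_channels: int = 8,
                         n_times: int = 500) -> dict:
    """Max relative error of forward-model synthesis -> MBLL inversion."""
    rng = np.random.default_rng(seed)
    hbo = 0.05 * rng.standard_normal((n_channels, n_times))
    hbr = 0.02 * rng.standard_normal((n_channels, n_times))
    intensity = forward_intensity(hbo, hbr, i0=1.0)
    rec_o, rec_r, _ = mbll_convert(intensity, i_ref=np.ones((n_channels, 3)))
    scale = max(np.abs(hbo).max(), np.abs(hbr).max())
    err = max(np.abs(rec_o - hbo).max(), np.abs(rec_r - hbr).max()) / scale
    return {"max_relative_error": float(err)}
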
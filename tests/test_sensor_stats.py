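"""Grand averages, channelwise ANOVA, HbO block t-tests, topographic maps."""

import numpy as np
import pytest
from scipy import stats

import neurointent as ni
from neurointent.sensor_stats import (
    DegenerateDataError,
    bonferroni,
    channel_anova,
    grand_average,
    hbo_block_ttest,
    topo_interpolate,
)


def _anova_oracle(groups):
    """From-scratch one-way ANOVA via sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def _epochs(data, labels, rate=50.0, window=(-0.5, 1.5), baseline=(-0.5, -0.3)):
    return ni.EpochSet(
        data=data, rate_hz=rate, labels=np.asarray(labels), modality="EEG",
        window_s=window, baseline_window_s=baseline,
    )


class TestGrandAverage:
    def test_single_trial_identity(self):
        data = np.random.default_rng(0).standard_normal((3, 2, 10))
        ep = _epochs(data, ["Sd", "Sm", "Su"])
        conds, ga = grand_average(ep)
        for i, c in enumerate(conds):
            assert np.array_equal(ga[i], data[list(ep.labels).index(c)])

    def test_constant_trials(self):
        ep = _epochs(np.full((6, 2, 10), 3.3), ["Sd", "Su"] * 3)
        _, ga = grand_average(ep)
        assert np.allclose(ga, 3.3)

    def test_planted_waveform_recovered_within_clt_bound(self):
        rng = np.random.default_rng(1)
        n_tr, sigma = 400, 1.0
        wave = np.sin(np.linspace(0, 2 * np.pi, 100))
        data = wave[None, None, :] + sigma * rng.standard_normal((n_tr, 1, 100))
        _, ga = grand_average(_epochs(data, ["Sd"] * n_tr))
        # 5 sigma of the mean's standard error
        assert np.max(np.abs(ga[0, 0] - wave)) < 5 * sigma / np.sqrt(n_tr)


class TestChannelAnova:
    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((30, 5, 40))
        labels = np.array(["Sd", "Sm", "Su"] * 10)
        ep = _epochs(data, labels)
        res = channel_anova(ep, (0.0, 0.5), alpha=0.05)
        mask = ep.time_mask(0.0, 0.5)
        means = data[:, :, mask].mean(axis=2)
        for ch in range(5):
            oracle = _anova_oracle([means[labels == c, ch] for c in ("Sd", "Sm", "Su")])
            assert res.statistic[ch] == pytest.approx(oracle, abs=1e-10)
        assert res.df == (2, 27)

    def test_separated_groups_with_jitter(self):
        # groups {1,1},{2,2},{3,3} with tiny jitter: huge F, all pairs significant
        base = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        jitter = np.array([1e-3, -1e-3, 1e-3, -1e-3, 1e-3, -1e-3])
        data = np.tile((base + jitter)[:, None, None], (1, 1, 100))
        ep = _epochs(data, ["Sd", "Sd", "Sm", "Sm", "Su", "Su"])
        res = channel_anova(ep, (0.0, 0.3), alpha=0.001)
        assert res.statistic[0] > 1e4
        assert np.all(res.posthoc_p[0] < 0.001)

    def test_identical_group_means_small_f(self):
        rng = np.random.default_rng(3)
        f_vals = []
        for _ in range(200):
            data = rng.standard_normal((30, 1, 50))
            ep = _epochs(data, ["Sd", "Sm", "Su"] * 10)
            f_vals.append(channel_anova(ep, (0.0, 0.1), alpha=0.05).statistic[0])
        # under the null E[F] = df_w / (df_w - 2) ~ 1.08
        assert np.mean(f_vals) == pytest.approx(27 / 25, abs=0.25)

    def test_type_one_error_rate_near_alpha(self):
        """Null data: channelwise rejection rate ~ alpha (simulation)."""
        rng = np.random.default_rng(4)
        n_ch = 400
        data = rng.standard_normal((30, n_ch, 50))
        ep = _epochs(data, ["Sd", "Sm", "Su"] * 10)
        res = channel_anova(ep, (0.0, 0.3), alpha=0.05)
        rate = res.significant.mean()
        se = np.sqrt(0.05 * 0.95 / n_ch)
        assert abs(rate - 0.05) <= 3 * se

    def test_degenerate_variance_rejected(self):
        data = np.zeros((6, 2, 60))
        data[[0, 1], :, :] = 1.0  # Sd trials constant 1, others constant 0
        ep = _epochs(data, ["Sd", "Sd", "Sm", "Sm", "Su", "Su"])
        with pytest.raises(DegenerateDataError):
            channel_anova(ep, (0.0, 0.1), alpha=0.05)

    def test_bonferroni_formula(self):
        p = np.array([0.001, 0.02, 0.5])
        assert np.allclose(bonferroni(p, 3), [0.003, 0.06, 1.0])


class TestHboBlockTtest:
    def _hbo_epochs(self, data, labels):
        return ni.EpochSet(
            data=data, rate_hz=1000 / 27, labels=np.asarray(labels),
            modality="HbO", window_s=(-6.5, 5.5), baseline_window_s=(-6.5, -0.5),
        )

    def test_planted_offset_gives_signed_t(self):
        rng = np.random.default_rng(5)
        n_t = 445
        data = 1e-6 * rng.standard_normal((20, 2, n_t))
        ep = self._hbo_epochs(data, ["Sd", "Sm"] * 10)
        t = ep.times_s
        data[:, 0, (t >= 0)] += 0.5  # positive offset channel 0
        data[:, 1, (t >= 0)] -= 0.5
        res = hbo_block_ttest(ep, times_s=(3.0,))
        assert res[3.0].statistic[0] > 1e3
        assert res[3.0].statistic[1] < -1e3

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        n_ch = 400
        data = rng.standard_normal((24, n_ch, 445))
        ep = self._hbo_epochs(data, ["Sd", "Sm", "Su"] * 8)
        res = hbo_block_ttest(ep, times_s=(3.0,), alpha=0.05)
        rate = res[3.0].significant.mean()
        se = np.sqrt(0.05 * 0.95 / n_ch)
        assert abs(rate - 0.05) <= 3 * se

    def test_planted_response_peaks_at_3s(self):
        """A generator subject's HbO response gives max |t| at the 3 s probe.

        Uses a wide analysis band and no latent state so the hemodynamic
        peak is the only structure.
        """
        from conftest import SMALL_PARADIGM

        gen = ni.GeneratorConfig(
            eeg_rate_hz=250.0, fnirs_latent_sigma=0.0
        )
        rec = ni.generate_subject(SMALL_PARADIGM, generator=gen, seed=7)
        hbo = ni.preprocessing.preprocess_fnirs(
            rec.fnirs_intensity, rec.fnirs_rate_hz, rec.schedule,
            band_hz=(0.01, 1.0),
        )["HbO"]
        res = hbo_block_ttest(hbo)
        mean_t = {t: r.statistic.mean() for t, r in res.items()}
        assert max(mean_t, key=mean_t.get) == 3.0


class TestTopoInterpolate:
    xy = np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.5]]
    )

    def test_constant_field(self):
        topo = topo_interpolate(np.full(5, 2.0), self.xy, grid_n=16)
        assert np.allclose(topo.grid[topo.mask], 2.0)
        assert topo.mask.any()

    def test_linear_field_reproduced_exactly(self):
        a, b = 2.0, -3.0
        vals = a * self.xy[:, 0] + b * self.xy[:, 1]
        topo = topo_interpolate(vals, self.xy, grid_n=16)
        gx, gy = np.meshgrid(topo.x, topo.y)
        expected = a * gx + b * gy
        assert np.allclose(topo.grid[topo.mask], expected[topo.mask], atol=1e-12)

    def test_exact_at_channel_sites(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal(5)
        topo = topo_interpolate(vals, self.xy, grid_n=8)
        assert np.allclose(topo.values_at_channels, vals, atol=1e-12)

    def test_collinear_layout_rejected(self):
        xy = np.column_stack([np.arange(4.0), np.arange(4.0)])
        with pytest.raises(DegenerateDataError):
            topo_interpolate(np.ones(4), xy)


def test_anova_significant_set_covers_responsive_channels(full_eeg_epochs):
    """Planted condition ordering makes all responsive channels ANOVA-
    significant at the EEG threshold (scaled check, one seed)."""
    res = channel_anova(full_eeg_epochs, (0.35, 0.40), alpha=0.001)
    responsive = np.arange(21, 64)
    assert res.significant[responsive].all()
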
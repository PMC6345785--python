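import numpy as np
import pytest

from rgcspeed import receptive_fields as rf
from rgcspeed import stimuli as st
from rgcspeed import synthetic_retina as sr


def _make_sta(kernel, frame_dt=1 / 60.0, px_per_mm=20.0, n_spikes=100):
    return rf.STA(
        kernel=kernel, n_lags=kernel.shape[0], frame_dt=frame_dt,
        n_spikes=n_spikes, px_per_mm=px_per_mm,
    )


def _planted_sta(a_mm=0.05, b_mm=0.05, polarity=1, n_lags=18, px_per_mm=20.0,
                 grid=35, temporal=(1.0, 0.5, 4.0, 7.0, 5.0)):
    cell = sr.GroundTruthCell(
        0, (grid / 2 / px_per_mm, grid / 2 / px_per_mm),
        a=max(a_mm, b_mm), b=min(a_mm, b_mm), angle=0.0, polarity=polarity,
        temporal_params=temporal, baseline_rate=1.0, gain=1.0,
    )
    return _make_sta(
        sr.cell_kernel(cell, (grid, grid), px_per_mm, n_lags),
        px_per_mm=px_per_mm,
    )


class TestComputeSTA:
    def test_single_spike_recovers_stimulus_segment(self, small_checkerboard):
        cb = small_checkerboard
        spike_frame = 100
        spike_t = (spike_frame + 0.5) / cb.frame_rate
        sta = rf.compute_sta(np.array([spike_t]), cb, n_lags=5)
        mean = cb.frames.mean()
        for j in range(5):
            assert np.allclose(
                sta.kernel[j], cb.frames[spike_frame - j] - mean
            )

    def test_zero_spikes_raises(self, small_checkerboard):
        with pytest.raises(ValueError):
            rf.compute_sta(np.array([]), small_checkerboard, n_lags=5)

    def test_random_spikes_give_null_sta(self, small_checkerboard):
        rng = np.random.default_rng(0)
        # spikes independent of the stimulus -> kernel shrinks as 1/sqrt(n)
        spikes = np.sort(
            rng.uniform(0.5, small_checkerboard.duration - 0.01, 10_000)
        )
        sta = rf.compute_sta(spikes, small_checkerboard, n_lags=10)
        stim_sd = small_checkerboard.frames.std()
        assert np.max(np.abs(sta.kernel)) < 3 * stim_sd / np.sqrt(sta.n_spikes) * 3

    def test_sta_linearity_in_spike_sets(self, small_checkerboard):
        rng = np.random.default_rng(1)
        s1 = np.sort(rng.uniform(0.5, 59.0, 400))
        s2 = np.sort(rng.uniform(0.5, 59.0, 600))
        sta1 = rf.compute_sta(s1, small_checkerboard, n_lags=6)
        sta2 = rf.compute_sta(s2, small_checkerboard, n_lags=6)
        both = rf.compute_sta(
            np.sort(np.concatenate([s1, s2])), small_checkerboard, n_lags=6
        )
        weighted = (
            sta1.n_spikes * sta1.kernel + sta2.n_spikes * sta2.kernel
        ) / (sta1.n_spikes + sta2.n_spikes)
        assert np.allclose(both.kernel, weighted, atol=1e-12)

    def test_ln_round_trip_recovers_planted_kernel(
        self, long_checkerboard, single_cell_population
    ):
        """1200-s reverse correlation recovers the generator kernel."""
        data = sr.simulate_ln_responses(
            single_cell_population, long_checkerboard, n_trials=1, seed=7
        )
        spikes = data.get(0, data.conditions[0], 0)
        sta = rf.denoise_sta(
            rf.compute_sta(spikes, long_checkerboard, n_lags=18)
        )
        planted = sr.cell_kernel(
            single_cell_population[0], (35, 35), long_checkerboard.px_per_mm, 18
        )
        corr = np.corrcoef(sta.kernel.ravel(), planted.ravel())[0, 1]
        assert corr > 0.9


class TestSpatialFit:
    def test_recovers_planted_isotropic_gaussian(self):
        sta = _planted_sta(a_mm=0.05, b_mm=0.05, polarity=1, grid=25)
        fit = rf.fit_spatial_rf(sta)
        assert fit.a == pytest.approx(0.05, rel=0.10)
        assert fit.b == pytest.approx(0.05, rel=0.10)
        assert fit.eccentricity < 0.2
        assert fit.valid

    def test_polarity_preserved(self):
        on = rf.fit_spatial_rf(_planted_sta(polarity=1, grid=25))
        off = rf.fit_spatial_rf(_planted_sta(polarity=-1, grid=25))
        assert on.polarity == 1 and off.polarity == -1

    def test_equivalent_radius_of_circle(self):
        fit = rf.fit_spatial_rf(_planted_sta(a_mm=0.06, b_mm=0.06, grid=25))
        assert fit.equivalent_radius == pytest.approx(
            np.sqrt(fit.a * fit.b), abs=1e-12
        )

    def test_eccentric_fit_flagged_invalid(self):
        sta = _planted_sta(a_mm=0.30, b_mm=0.04, grid=45)
        fit = rf.fit_spatial_rf(sta)
        assert fit.eccentricity > 0.9
        assert not fit.valid

    def test_discard_rule_exact_on_planted_eccentricities(self):
        rng = np.random.default_rng(3)
        eccs = rng.uniform(0.0, 1.0, 200)
        kept = eccs[eccs <= rf.ECCENTRICITY_MAX]
        assert kept.size == np.sum(eccs <= 0.9)


class TestEccentricity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(1.0, 1.0, 0.0), (2.0, 1.0, 0.8660254037844386), (5.0, 3.0, 0.8)],
    )
    def test_values(self, a, b, expected):
        assert rf.ellipse_eccentricity(a, b) == pytest.approx(expected, abs=1e-9)

    def test_swapped_arguments_warn(self):
        with pytest.warns(RuntimeWarning):
            e = rf.ellipse_eccentricity(1.0, 2.0)
        assert e == pytest.approx(0.8660254037844386)

    def test_nonpositive_axis_raises(self):
        with pytest.raises(ValueError):
            rf.ellipse_eccentricity(1.0, 0.0)


class TestTemporalFit:
    def test_noiseless_cascade_recovery(self):
        """Planted (p1=1, p2=0.8, tau1=4, tau2=6, n=6) recovered within 5%."""
        params = (1.0, 0.8, 4.0, 6.0, 6.0)
        sta = _planted_sta(temporal=params, grid=15, n_lags=24)
        fit = rf.fit_temporal_profile(sta)
        # the time course is normalized to unit dominant-lobe amplitude,
        # so amplitudes are compared after the same normalization
        t = np.arange(24, dtype=float)
        curve = rf.cascade_difference(t, *params)
        scale = np.abs(curve).max()
        assert fit.tau1 == pytest.approx(4.0, rel=0.05)
        assert fit.tau2 == pytest.approx(6.0, rel=0.05)
        assert fit.n == pytest.approx(6.0, rel=0.05)
        assert fit.p1 == pytest.approx(1.0 / scale, rel=0.05)
        assert fit.p2 == pytest.approx(0.8 / scale, rel=0.05)

    def test_monophasic_has_no_zero_cross(self):
        sta = _planted_sta(temporal=(1.0, 0.0, 5.0, 8.0, 6.0), grid=15, n_lags=24)
        fit = rf.fit_temporal_profile(sta)
        assert fit.zero_cross is None

    def test_fitted_sign_sequence_matches_input(self):
        params = (1.0, 0.6, 4.0, 7.0, 5.0)
        sta = _planted_sta(temporal=params, grid=15, n_lags=24)
        fit = rf.fit_temporal_profile(sta)
        t = np.arange(1, 24, dtype=float)
        y = rf.cascade_difference(t, *params)
        model = rf.cascade_difference(t, fit.p1, fit.p2, fit.tau1, fit.tau2, fit.n)
        big = np.abs(y) > 0.05 * np.abs(y).max()
        assert np.all(np.sign(model[big]) == np.sign(y[big]))


class TestMarkers:
    def test_single_cascade_peaks_at_tau(self):
        fit = rf.TemporalRFFit(
            p1=1.0, p2=0.0, tau1=5.0, tau2=8.0, n=6.0, zero_cross=None,
            peak_time=np.nan, fit_residual=0.0, frame_dt=1 / 60.0,
        )
        zc, pk = rf.temporal_markers(fit)
        assert pk == pytest.approx(5.0 / 60.0, rel=1e-3)
        assert zc is None

    def test_zero_cross_matches_dense_grid_search(self):
        params = (1.0, 0.8, 4.0, 6.0, 6.0)
        fit = rf.TemporalRFFit(
            p1=params[0], p2=params[1], tau1=params[2], tau2=params[3],
            n=params[4], zero_cross=None, peak_time=np.nan,
            fit_residual=0.0, frame_dt=1 / 60.0,
        )
        zc, pk = rf.temporal_markers(fit)
        # dense-grid oracle for the first sign change after the peak
        t = np.linspace(1e-6, 20, 200_001)
        y = rf.cascade_difference(t, *params)
        peak_idx = np.argmax(np.abs(y))
        after = t > t[peak_idx]
        s = np.sign(y[after])
        flip = np.nonzero(s[:-1] * s[1:] < 0)[0][0]
        zc_oracle = t[after][flip] / 60.0
        assert zc == pytest.approx(zc_oracle, abs=0.1 / 60.0)

    def test_marker_distributions_ks_separation(self):
        """KS flags a zero-cross shift but not matched peak times."""
        rng = np.random.default_rng(8)
        zc_a = rng.normal(0.12, 0.01, 60)
        zc_b = rng.normal(0.15, 0.01, 60)
        pk = rng.normal(0.06, 0.008, 60)
        _, p_zc = rf.compare_marker_distributions(zc_a, zc_b)
        _, p_pk = rf.compare_marker_distributions(pk, rng.permutation(pk))
        assert p_zc < 0.01
        assert p_pk > 0.2
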
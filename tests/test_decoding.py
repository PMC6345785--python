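import numpy as np
import pytest

from rgcspeed import decoding as dec
from rgcspeed import receptive_fields as rf
from rgcspeed import stimuli as st
from rgcspeed import synthetic_retina as sr

SPEEDS = (0.25, 0.5, 1.0, 2.0, 4.0)
PX_PER_MM = 30.0
DT = 1 / 60.0


def _sta_from_kernel(kernel, px_per_mm=20.0):
    return rf.STA(kernel=kernel, n_lags=kernel.shape[0], frame_dt=DT,
                  n_spikes=1, px_per_mm=px_per_mm)


def _xt_sine(sf, v, T=180, X=160, px_per_mm=PX_PER_MM):
    t = np.arange(T) * DT
    x = np.arange(X) / px_per_mm
    return np.sin(2 * np.pi * sf * (x[None, :] - v * t[:, None]))


class TestCollapse:
    def test_separable_kernel_preserved(self):
        temporal = rf.cascade_difference(np.arange(12.0), 1, 0.6, 4, 7, 5)
        spatial = np.exp(
            -0.5 * ((np.arange(20) - 10) ** 2 / 9.0)[:, None]
            - 0.5 * ((np.arange(24) - 12) ** 2 / 16.0)[None, :]
        )
        kernel = temporal[:, None, None] * spatial[None]
        collapsed = dec.collapse_rf(_sta_from_kernel(kernel))
        expected = temporal[:, None] * spatial.mean(axis=0)[None, :]
        assert np.allclose(collapsed, expected)

    def test_invariant_to_orthogonal_shift(self):
        temporal = rf.cascade_difference(np.arange(12.0), 1, 0.6, 4, 7, 5)
        col = np.exp(-0.5 * (np.arange(24) - 12) ** 2 / 16.0)
        row_a = np.zeros(20); row_a[5] = 1.0
        row_b = np.zeros(20); row_b[13] = 1.0
        ka = temporal[:, None, None] * (row_a[:, None] * col[None, :])[None]
        kb = temporal[:, None, None] * (row_b[:, None] * col[None, :])[None]
        assert np.allclose(
            dec.collapse_rf(_sta_from_kernel(ka)),
            dec.collapse_rf(_sta_from_kernel(kb)),
        )

    def test_collapsed_centroid_matches_planted_center(self):
        cell = sr.GroundTruthCell(
            0, (0.8, 0.4), a=0.08, b=0.08, angle=0.0, polarity=1,
            temporal_params=(1, 0.5, 4, 7, 5), baseline_rate=1, gain=1,
        )
        kernel = sr.cell_kernel(cell, (40, 40), 20.0, 12)
        collapsed = dec.collapse_rf(_sta_from_kernel(kernel))
        profile = np.abs(collapsed).sum(axis=0)
        centroid_px = (np.arange(40) * profile).sum() / profile.sum()
        assert abs(centroid_px - 0.8 * 20.0) < 1.0


class TestReconstruction:
    def test_no_spikes_is_flat_offset(self):
        counts = {0: np.zeros(30)}
        kernels = {0: np.ones((5, 8))}
        recon = dec.reconstruct_xt(counts, kernels, offset=0.5)
        assert np.allclose(recon.intensity, 0.5)

    def test_single_spike_paints_kernel(self):
        k = np.arange(40.0).reshape(5, 8)
        counts = {0: np.zeros(30)}
        counts[0][7] = 1.0
        recon = dec.reconstruct_xt(counts, {0: k}, offset=0.0)
        for j in range(5):
            assert np.allclose(recon.intensity[7 + j], k[j])
        assert np.allclose(recon.intensity[:7], 0.0)

    def test_linearity_in_spike_trains(self):
        rng = np.random.default_rng(0)
        k = {0: rng.normal(size=(6, 10)), 1: rng.normal(size=(6, 10))}
        r1 = {c: rng.poisson(1.0, 40).astype(float) for c in k}
        r2 = {c: rng.poisson(1.0, 40).astype(float) for c in k}
        r12 = {c: r1[c] + r2[c] for c in k}
        a = 0.5
        i1 = dec.reconstruct_xt(r1, k, offset=a).intensity
        i2 = dec.reconstruct_xt(r2, k, offset=a).intensity
        i12 = dec.reconstruct_xt(r12, k, offset=a).intensity
        assert np.allclose(i12 - a, (i1 - a) + (i2 - a), atol=1e-9)

    def test_missing_kernel_raises(self):
        with pytest.raises(KeyError):
            dec.reconstruct_xt({0: np.zeros(10)}, {}, offset=0.0)


class TestBank:
    def test_five_speed_channels(self):
        bank = dec.build_motion_energy_bank(SPEEDS, 0.9, px_per_mm=PX_PER_MM)
        assert set(bank.kernels) == set(SPEEDS)

    def test_kernels_zero_mean_unit_energy_quadrature(self):
        bank = dec.build_motion_energy_bank(SPEEDS, 0.9, px_per_mm=PX_PER_MM)
        for even, odd in bank.kernels.values():
            assert abs(even.mean()) < 1e-12 and abs(odd.mean()) < 1e-12
            assert np.linalg.norm(even) == pytest.approx(1.0)
            assert np.linalg.norm(odd) == pytest.approx(1.0)

    def test_quadrature_energy_is_phase_invariant(self):
        from scipy import signal as sg
        bank = dec.build_motion_energy_bank((1.0,), 0.9, px_per_mm=PX_PER_MM)
        even, odd = bank.kernels[1.0]
        I = _xt_sine(0.9, 1.0)
        re = sg.fftconvolve(I, even[::-1, ::-1], mode="valid")
        ro = sg.fftconvolve(I, odd[::-1, ::-1], mode="valid")
        energy = re**2 + ro**2
        assert (energy.max() - energy.min()) / energy.mean() < 0.05

    def test_mirror_symmetry_matches_opposite_direction(self):
        bank = dec.build_motion_energy_bank((1.0,), 0.9, px_per_mm=PX_PER_MM)
        even, _ = bank.kernels[1.0]
        neg_even, _ = dec._gabor_pair(-1.0, 0.9, DT, PX_PER_MM,
                                      1 / (2 * 0.9), even.shape[0] // 2 * DT / 2.5)
        # construction symmetry: mirroring x reverses the preferred direction
        assert np.allclose(even[:, ::-1], neg_even, atol=1e-12)

    def test_duplicate_speeds_rejected(self):
        with pytest.raises(ValueError):
            dec.build_motion_energy_bank((1.0, 1.0), 0.9)

    def test_kernel_exceeding_grid_raises(self):
        with pytest.raises(ValueError):
            dec.build_motion_energy_bank(
                (0.25,), 0.9, px_per_mm=PX_PER_MM, grid_shape=(10, 10)
            )


class TestDecode:
    @pytest.mark.parametrize("v", SPEEDS)
    def test_sinusoid_decoded_at_true_speed(self, v):
        bank = dec.build_motion_energy_bank(SPEEDS, 0.9, px_per_mm=PX_PER_MM)
        d = dec.decode_speed(_xt_sine(0.9, v), bank)
        assert d.chosen_speed == v
        assert d.direction == 1

    def test_static_pattern_gives_no_decision(self):
        bank = dec.build_motion_energy_bank(SPEEDS, 0.9, px_per_mm=PX_PER_MM)
        x = np.arange(160) / PX_PER_MM
        static = np.tile(np.sin(2 * np.pi * 0.9 * x), (180, 1))
        d = dec.decode_speed(static, bank)
        assert d.chosen_speed is None

    def test_time_reversal_flips_direction_keeps_speed(self):
        bank = dec.build_motion_energy_bank(SPEEDS, 0.9, px_per_mm=PX_PER_MM)
        I = _xt_sine(0.9, 1.0)
        fwd = dec.decode_speed(I, bank)
        rev = dec.decode_speed(I[::-1], bank)
        assert rev.chosen_speed == fwd.chosen_speed == 1.0
        assert rev.direction == -fwd.direction

    def test_opponent_antisymmetry(self):
        bank = dec.build_motion_energy_bank(SPEEDS, 0.9, px_per_mm=PX_PER_MM)
        d = dec.decode_speed(_xt_sine(0.9, 2.0), bank)
        for v, (e_pos, e_neg) in d.energies.items():
            assert d.net_energy[v] == pytest.approx(e_pos - e_neg)


class TestMetrics:
    def test_error_rate(self):
        decisions = [(1.0, 1.0)] * 7 + [(1.0, 2.0)] * 3
        m = dec.decoding_metrics(decisions, total_spikes=100, n_cells=10)
        assert m["error_rate"] == pytest.approx(0.3)

    def test_all_correct(self):
        m = dec.decoding_metrics([(1.0, 1.0)] * 5, 50, 5)
        assert m["error_rate"] == 0.0

    def test_accuracy_cost(self):
        decisions = [(1.0, 1.0)] * 7 + [(1.0, None)] * 3
        m = dec.decoding_metrics(decisions, total_spikes=1000, n_cells=100)
        assert m["accuracy_cost"] == pytest.approx(7.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dec.decoding_metrics([], 0, 1)


@pytest.fixture(scope="module")
def loop():
    size_px, n_lags = 120, 18
    pop = sr.make_ground_truth_population(
        n_cells=120, on_fraction=0.5, field_size=size_px / PX_PER_MM,
        baseline_rate=0.0, gain=150.0, seed=3,
    )
    kernels = {
        c.cell_id: dec.collapse_rf(_sta_from_kernel(
            sr.cell_kernel(c, (size_px, size_px), PX_PER_MM, n_lags),
            px_per_mm=PX_PER_MM,
        ))
        for c in pop
    }
    return pop, kernels, size_px


class TestClosedLoop:
    def test_noiseless_grating_decoded_end_to_end(self, loop):
        """Simulate -> reconstruct -> decode returns the true speed."""
        pop, kernels, size_px = loop
        sf0 = 1.26
        bank = dec.build_motion_energy_bank(SPEEDS, sf0, px_per_mm=PX_PER_MM)
        for v in (0.5, 1.0, 2.0):
            movie = st.make_drifting_grating(
                sf0, v, size_px=size_px, px_per_mm=PX_PER_MM
            )
            data = sr.simulate_ln_responses(
                pop, movie, n_trials=1, seed=1, poisson=False
            )
            counts = data.meta["expected_counts"]
            recon = dec.reconstruct_xt(
                counts, kernels, offset=0.5, px_per_mm=PX_PER_MM
            )
            assert dec.decode_speed(recon, bank).chosen_speed == v

    def test_error_rate_degrades_with_gain(self, loop):
        """Lower firing gain cannot improve Poisson decoding accuracy."""
        pop, kernels, size_px = loop
        sf0 = 1.26
        bank = dec.build_motion_energy_bank(SPEEDS, sf0, px_per_mm=PX_PER_MM)
        errors = {}
        for gain in (150.0, 2.0):
            for c in pop:
                c.gain = gain
            wrong = 0
            trials = 0
            for v in (0.5, 2.0):
                movie = st.make_drifting_grating(
                    sf0, v, size_px=size_px, px_per_mm=PX_PER_MM
                )
                data = sr.simulate_ln_responses(
                    pop, movie, n_trials=3, seed=17
                )
                cond = data.conditions[0]
                for t in range(3):
                    counts = {
                        c.cell_id: dec.bin_spike_counts(
                            data.get(c.cell_id, cond, t), movie.duration
                        )
                        for c in pop
                    }
                    recon = dec.reconstruct_xt(
                        counts, kernels, offset=0.5, px_per_mm=PX_PER_MM
                    )
                    wrong += dec.decode_speed(recon, bank).chosen_speed != v
                    trials += 1
            errors[gain] = wrong / trials
        for c in pop:
            c.gain = 150.0
        assert errors[2.0] >= errors[150.0]
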
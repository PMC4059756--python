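"""Simulator: bolus model, tracer kinetics, calibration, dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dscaif import (
    AcquisitionParams,
    AifModelParams,
    NoiseSpec,
    SimulationConfig,
    TimeGrid,
    TissueClassSpec,
    VoxelLabel,
    build_dataset,
    gamma_variate,
    make_false_aifs,
    make_true_aif,
)
from dscaif.simulate import (
    add_noise,
    calibrate_k,
    concentration_to_signal,
    gamma_variate_peak,
    mix_pve,
    residue_function,
    tissue_concentration,
)
from oracles import fine_grid_gamma_peak


class TestGammaVariate:
    def test_peak_matches_closed_form_and_fine_grid_oracle(self):
        peak_analytic = gamma_variate_peak(3.0, 1.5)
        peak_oracle, t_oracle = fine_grid_gamma_peak(26.0, 3.0, 1.5)
        assert peak_analytic == pytest.approx(4.5369, abs=1e-4)
        assert peak_analytic == pytest.approx(peak_oracle, abs=1e-6)
        assert t_oracle == pytest.approx(26.0 + 3.0 * 1.5, abs=1e-3)

    @pytest.mark.parametrize(
        "t, expected",
        [(30.5, 4.5369), (26.0, 0.0), (27.0, np.exp(-2.0 / 3.0)), (20.0, 0.0)],
    )
    def test_point_values(self, t, expected):
        assert gamma_variate(t, 26.0, 3.0, 1.5) == pytest.approx(expected, abs=1e-4)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            gamma_variate(np.array([1.0, np.nan]), 26.0, 3.0, 1.5)
        with pytest.raises(ValueError):
            gamma_variate(30.0, 26.0, -1.0, 1.5)
        with pytest.raises(ValueError):
            gamma_variate(30.0, 26.0, 3.0, 0.0)


class TestTrueAif:
    def test_peak_near_continuous_maximum_on_fine_grid(self):
        fine = TimeGrid(dt=0.01)
        curve = make_true_aif(fine)
        assert curve.max() == pytest.approx(4.5369, rel=0.02)

    def test_causal_before_arrival(self, grid, true_aif):
        t = grid.times
        assert np.all(true_aif[t < 26.0] == 0.0)
        assert np.all(true_aif >= 0.0)

    def test_recirculation_beyond_grid_reduces_to_first_passage(self, grid):
        p = AifModelParams(recirc_delay=500.0)
        np.testing.assert_allclose(
            make_true_aif(grid, p), gamma_variate(grid.times, 26.0, 3.0, 1.5)
        )

    def test_recirculation_adds_tail_mass(self, grid, true_aif):
        first = gamma_variate(grid.times, 26.0, 3.0, 1.5)
        assert np.all(true_aif >= first)
        assert true_aif[60] > first[60]


class TestFalseAifs:
    def test_full_cartesian_product(self, grid):
        curves, params = make_false_aifs(grid)
        assert curves.shape == (16, grid.n_points)
        combos = {(p.t0, p.recirc_delay) for p in params}
        assert combos == {(t0, d) for t0 in (27, 28, 29, 30) for d in (9, 10, 11, 12)}

    def test_later_onset_than_true_aif(self, grid, true_aif):
        curves, params = make_false_aifs(grid)
        t = grid.times
        for curve, p in zip(curves, params):
            assert np.all(curve[t <= p.t0] == 0.0)
            assert p.t0 > 26.0


class TestResidueFunction:
    def test_exponential_member_integrates_to_mtt(self, grid):
        r = residue_function(grid, mtt=4.0)
        assert 3.92 <= np.trapezoid(r, grid.times) <= 4.08

    @pytest.mark.parametrize("shape", [0.0, 1.0, 3.0])
    def test_starts_at_one_and_non_increasing(self, grid, shape):
        r = residue_function(grid, mtt=4.0, shape=shape)
        assert r[0] == pytest.approx(1.0)
        assert np.all(np.diff(r) <= 1e-12)

    @pytest.mark.parametrize("shape", [1.0, 3.0])
    def test_gamma_family_keeps_mean_transit_time(self, grid, shape):
        r = residue_function(grid, mtt=4.0, shape=shape)
        assert np.trapezoid(r, grid.times) == pytest.approx(4.0, rel=0.02)

    def test_slower_washout_dominates_pointwise(self, grid):
        r4 = residue_function(grid, 4.0)
        r10 = residue_function(grid, 10.0)
        assert np.all(r10[1:] >= r4[1:])

    def test_rejects_nonpositive_mtt(self, grid):
        with pytest.raises(ValueError):
            residue_function(grid, 0.0)


class TestTissueConcentration:
    def test_peak_lower_and_later_than_arterial(self, grid, true_aif):
        ct = tissue_concentration(true_aif, cbv=4.0, mtt=4.0, grid=grid)
        assert ct.max() < true_aif.max()
        assert np.argmax(ct) > np.argmax(true_aif)
        assert ct[0] == 0.0
        assert np.all(ct >= 0.0)

    def test_linear_in_aif_and_cbv(self, grid, true_aif):
        ct = tissue_concentration(true_aif, 4.0, 4.0, grid)
        np.testing.assert_allclose(
            tissue_concentration(2.0 * true_aif, 4.0, 4.0, grid), 2.0 * ct
        )
        np.testing.assert_allclose(tissue_concentration(true_aif, 8.0, 4.0, grid), 2.0 * ct)
        assert tissue_concentration(np.zeros_like(true_aif), 4.0, 4.0, grid).max() == 0.0

    def test_grid_mismatch_raises(self, grid, true_aif):
        with pytest.raises(ValueError):
            tissue_concentration(true_aif[:-1], 4.0, 4.0, grid)


class TestCalibration:
    def test_grey_matter_trough_is_forty_percent_below_baseline(self, grid, true_aif):
        gm = TissueClassSpec("normal_GM", 4.0, 4.0, 0.33, 440)
        k = calibrate_k(grid, true_aif, gm)
        ct = tissue_concentration(true_aif, gm.cbv, gm.mtt_mean, grid)
        s = concentration_to_signal(ct, AcquisitionParams(100.0, 0.030, k))
        assert s.min() == pytest.approx(60.0, abs=1e-9)

    def test_inverse_proportionality_in_peak(self, grid, true_aif):
        gm = TissueClassSpec("normal_GM", 4.0, 4.0, 0.33, 440)
        k1 = calibrate_k(grid, true_aif, gm)
        k2 = calibrate_k(grid, 2.0 * true_aif, gm)  # doubles the tissue peak
        assert k2 == pytest.approx(k1 / 2.0)

    def test_zero_concentration_keeps_baseline(self, grid):
        s = concentration_to_signal(np.zeros(grid.n_points), AcquisitionParams())
        np.testing.assert_allclose(s, 100.0)


class TestMixPve:
    @given(w=st.floats(0.0, 1.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_mixture_bounded_by_components(self, w):
        a = np.array([1.0, 5.0, 2.0])
        t = np.array([3.0, 1.0, 2.0])
        m = mix_pve(a, t, w)
        assert np.all(m >= np.minimum(a, t) - 1e-12)
        assert np.all(m <= np.maximum(a, t) + 1e-12)

    def test_endpoints_and_midpoint(self):
        a, t = np.array([1.0, 2.0]), np.array([3.0, 0.0])
        np.testing.assert_allclose(mix_pve(a, t, 1.0), a)
        np.testing.assert_allclose(mix_pve(a, t, 0.0), t)
        np.testing.assert_allclose(mix_pve(a, t, 0.5), [2.0, 1.0])

    def test_rejects_weight_outside_unit_interval(self):
        with pytest.raises(ValueError):
            mix_pve(np.ones(3), np.ones(3), 1.5)


class TestAddNoise:
    def test_noise_sd_is_s0_over_snr(self, rng):
        signals = np.full((200, 500), 100.0)
        noisy, idx = add_noise(signals, NoiseSpec(20.0, 100), 100.0, rng)
        assert idx.size == 100
        resid = noisy[idx] - 100.0
        assert resid.std() == pytest.approx(5.0, rel=0.02)
        untouched = np.setdiff1d(np.arange(200), idx)
        np.testing.assert_array_equal(noisy[untouched], signals[untouched])

    def test_zero_noisy_curves_is_identity(self, rng):
        signals = np.random.default_rng(0).random((10, 5))
        noisy, idx = add_noise(signals, NoiseSpec(20.0, 0), 100.0, rng)
        np.testing.assert_array_equal(noisy, signals)
        assert idx.size == 0

    def test_seeded_rng_reproducible(self):
        signals = np.full((50, 20), 100.0)
        a, ia = add_noise(signals, NoiseSpec(40.0, 10), 100.0, np.random.default_rng(7))
        b, ib = add_noise(signals, NoiseSpec(40.0, 10), 100.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ia, ib)


class TestBuildDataset:
    def test_population_counts(self, default_dataset):
        ds = default_dataset
        assert ds.signals.shape == (1902, 90)
        expected = {
            "true_arterial": 6, "false_arterial": 16, "normal_GM": 440,
            "path_GM": 440, "WM": 600, "pve_mix": 400,
        }
        classes, counts = np.unique(ds.classes, return_counts=True)
        assert dict(zip(classes.tolist(), counts.tolist())) == expected

    def test_true_arterial_rows_identical_before_noise(self, default_dataset):
        ds = default_dataset
        clean = [i for i in range(6) if i not in ds.noisy_indices]
        assert len(clean) >= 2
        for i in clean[1:]:
            np.testing.assert_array_equal(ds.signals[clean[0]], ds.signals[i])

    def test_same_seed_bit_identical(self):
        a = build_dataset(seed=42)
        b = build_dataset(seed=42)
        np.testing.assert_array_equal(a.signals, b.signals)
        np.testing.assert_array_equal(a.noisy_indices, b.noisy_indices)
        assert a.labels == b.labels

    def test_different_seeds_differ(self):
        a = build_dataset(seed=1)
        b = build_dataset(seed=2)
        assert not np.array_equal(a.signals, b.signals)
        # the deterministic skeleton (true AIF, calibration) is unchanged
        np.testing.assert_array_equal(a.true_aif, b.true_aif)
        assert a.k_const == b.k_const

    def test_mix_weights_present_only_for_pve(self, default_dataset):
        for lab in default_dataset.labels:
            assert (lab.cls == "pve_mix") == (lab.mix_weight is not None)
            if lab.mix_weight is not None:
                assert 0.0 <= lab.mix_weight <= 1.0

    def test_signals_positive_under_magnitude_noise(self, default_dataset):
        assert np.all(default_dataset.signals >= 0.0)


def test_voxel_label_invariant():
    with pytest.raises(ValueError):
        VoxelLabel("pve_mix")
    with pytest.raises(ValueError):
        VoxelLabel("WM", mix_weight=0.5)


def test_time_grid_invariants():
    g = TimeGrid()
    assert g.n_points == 90
    assert np.all(np.diff(g.times) == 1.0)
    with pytest.raises(ValueError):
        TimeGrid(dt=-1.0)
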
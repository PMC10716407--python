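"""Kinetics, probe-volume sampling, offline-reference and renderer tests."""

import math

import numpy as np
import pytest

from ismpop import (
    BioprocessTrajectory,
    CellSpec,
    ConfusionSpec,
    InitialState,
    IntegrationError,
    KineticParameters,
    OfflineNoise,
    OpticsParameters,
    ProcessEvent,
    generate_offline_reference,
    growth_influx,
    render_micrograph,
    sample_ism_counts,
    simulate_bioprocess,
    single_cell_frame,
)
from ismpop.core import CLASS_COLUMNS
from ismpop.validation import coefficient_of_variation


def _constant_trajectory(densities, t_end=10.0, n=101):
    times = np.linspace(0.0, t_end, n)
    dens = np.tile(np.asarray(densities, dtype=float), (n, 1))
    return BioprocessTrajectory(
        times=times,
        densities=dens,
        substrate=np.full(n, 2.0),
        dissolved_oxygen=np.full(n, 30.0),
    )


class TestSimulateBioprocess:
    def test_zero_rates_is_fixed_point(self, quiet_params):
        init = InitialState()
        traj = simulate_bioprocess(quiet_params, [], init, t_end=20.0, dt=0.1)
        np.testing.assert_allclose(
            traj.densities, np.tile(traj.densities[0], (len(traj.times), 1)), rtol=1e-6
        )
        np.testing.assert_allclose(
            traj.substrate, np.full_like(traj.substrate, traj.substrate[0]), rtol=1e-6
        )

    def test_unlimited_growth_is_exponential(self, growth_only_params, simple_init):
        traj = simulate_bioprocess(growth_only_params, [], simple_init, t_end=60.0, dt=0.05)
        for t in (10.0, 30.0, 60.0):
            i = int(round(t / 0.05))
            expected = simple_init.viable * math.exp(0.04 * t)
            assert traj.densities[i, 0] == pytest.approx(expected, rel=1e-8)

    def test_doubling_time_matches_growth_rate(self, growth_only_params, simple_init):
        # ln 2 / 0.04 ≈ 17.3 h
        traj = simulate_bioprocess(growth_only_params, [], simple_init, t_end=40.0, dt=0.05)
        t_double = math.log(2.0) / 0.04
        i = int(round(t_double / 0.05))
        ratio = traj.densities[i, 0] / traj.densities[0, 0]
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_washout_when_dilution_exceeds_growth(self, simple_init):
        params = KineticParameters(D=0.05)   # > mu_max = 0.04, chemostat from t=0
        traj = simulate_bioprocess(params, [], simple_init, t_end=400.0, dt=0.05)
        viable = traj.viable_total
        assert np.all(np.diff(viable) <= 1e-9 * viable[0])
        assert viable[-1] < 0.01 * viable[0]

    def test_parameter_errors(self, quiet_params):
        with pytest.raises(ValueError):
            simulate_bioprocess(quiet_params, [], InitialState(), t_end=10.0, dt=-0.1)
        with pytest.raises(ValueError):
            InitialState(viable=-1.0).as_vector()
        with pytest.raises(ValueError):
            KineticParameters(k_late=-0.1)

    def test_oversized_step_fails_loudly(self, simple_init):
        # substrate overshoots negative with a tiny yield and a 1-h step
        params = KineticParameters(yield_cells_per_g=1e3)
        with pytest.raises(IntegrationError):
            simulate_bioprocess(params, [], simple_init, t_end=10.0, dt=1.0)

    def test_mass_accounting_total_changes_by_growth_influx_only(self):
        # no lysis, no dilution: d(total)/dt == growth influx, to 1e-6 relative
        params = KineticParameters(k_lysis=0.0, D=0.0)
        init = InitialState()
        dt = 0.002
        traj = simulate_bioprocess(params, [], init, t_end=2.0, dt=dt)
        total = traj.densities.sum(axis=1)
        deriv = (total[2:] - total[:-2]) / (2 * dt)
        states = np.column_stack(
            [traj.densities, traj.substrate, traj.dissolved_oxygen]
        )
        influx = np.array(
            [growth_influx(states[i], params, [], traj.times[i])
             for i in range(1, len(total) - 1)]
        )
        np.testing.assert_allclose(deriv, influx, rtol=1e-6)

    def test_feast_famine_transition_reverses_after_event(self):
        params = KineticParameters()
        init = InitialState()
        event = ProcessEvent("pulse", "medium_addition", 10.0, 10.5, 1.0)
        traj = simulate_bioprocess(params, [event], init, t_end=45.0, dt=0.05)
        share = traj.densities[:, 1] / traj.viable_total

        i_pre = int(round(10.0 / 0.05))
        i_peak = int(round(11.0 / 0.05))
        i_post = int(round(42.0 / 0.05))
        assert share[i_peak] > share[i_pre]          # net flux into bulged pool
        assert abs(share[i_post] - share[i_pre]) < 0.10 * share[i_pre]

    def test_oxygen_depletion_raises_death_influx(self):
        params = KineticParameters()
        init = InitialState()
        event = ProcessEvent("o2_off", "oxygen_depletion", 5.0, 15.0, 1.0)
        base = simulate_bioprocess(params, [], init, t_end=20.0, dt=0.05)
        hit = simulate_bioprocess(params, [event], init, t_end=20.0, dt=0.05)
        i = int(round(15.0 / 0.05))
        assert hit.densities[i, 3] > base.densities[i, 3]   # apoptotic
        assert hit.densities[i, 4] > base.densities[i, 4]   # necrotic


class TestSampleIsmCounts:
    def test_zero_density_gives_zero_counts(self):
        traj = _constant_trajectory(np.zeros(6))
        counts = sample_ism_counts(traj, alpha=3.2e6, n_images_per_point=50, seed=1)
        assert counts.raw_reported.sum() == 0

    def test_poisson_moments(self):
        # one class at 6.4e5 cell/mL with alpha 3.2e6 -> 0.2 cells/image
        dens = np.zeros(6)
        dens[0] = 6.4e5
        traj = _constant_trajectory(dens, n=2)
        counts = sample_ism_counts(
            traj, alpha=3.2e6, n_images_per_point=100_000, seed=7,
            sample_times=[5.0],
        )
        raw = counts.raw_reported[0, 0]
        lam = 0.2
        se_mean = math.sqrt(lam / raw.size)
        assert abs(raw.mean() - lam) < 3 * se_mean
        se_var = math.sqrt((lam + 2 * lam ** 2) / raw.size)
        assert abs(raw.var() - lam) < 3 * se_var

    def test_identity_confusion_reports_true_counts(self):
        traj = _constant_trajectory(np.full(6, 2.0e5))
        counts = sample_ism_counts(traj, 3.2e6, 200, ConfusionSpec.identity(), seed=3)
        np.testing.assert_array_equal(counts.raw_reported, counts.raw_true)

    def test_confusion_must_be_row_stochastic(self):
        m = np.eye(6)
        m[0, 0] = 0.5
        with pytest.raises(ValueError):
            ConfusionSpec(m)

    def test_confusion_shifts_reported_classes(self):
        dens = np.zeros(6)
        dens[0] = 6.4e5      # viable column only
        traj = _constant_trajectory(dens, n=2)
        conf = ConfusionSpec.symmetric_swap(1, 4, 0.25)
        counts = sample_ism_counts(traj, 3.2e6, 20_000, conf, seed=5, sample_times=[5.0])
        true_total = counts.raw_true[0, 0].sum()
        reported_bulged = counts.raw_reported[0, 1].sum()
        assert reported_bulged / true_total == pytest.approx(0.25, abs=0.02)

    def test_poisson_thinning_halves_agree(self):
        dens = np.full(6, 3.0e5)
        traj = _constant_trajectory(dens, n=2)
        counts = sample_ism_counts(traj, 3.2e6, 2000, seed=11, sample_times=[5.0])
        raw = counts.raw_reported[0].sum(axis=0)      # per image, all classes
        half = raw.size // 2
        a, b = raw[:half].sum(), raw[half:].sum()
        total = raw.sum()
        assert total > 100
        assert abs(a - b) < 4 * math.sqrt(total)


class TestOfflineReference:
    def test_noiseless_samples_equal_truth(self, default_trajectory):
        times = [5.0, 50.0, 100.0]
        samples = generate_offline_reference(
            default_trajectory, times, OfflineNoise.noiseless(), seed=0
        )
        truth = default_trajectory.interpolate(times)
        for s, row in zip(samples, truth):
            assert s.density == pytest.approx(row.sum(), rel=1e-12)

    def test_low_viability_cv_matches_configured_value(self):
        # constant composition with 27% viability; 500 replicate samples
        dens = np.array([0.20, 0.05, 0.02, 0.40, 0.23, 0.10]) * 1e6
        viab = 100 * dens[:3].sum() / dens.sum()
        assert viab == pytest.approx(27.0, abs=0.1)
        traj = _constant_trajectory(dens)
        samples = generate_offline_reference(
            traj, np.full(500, 5.0), OfflineNoise(), seed=21
        )
        cv = coefficient_of_variation([s.viability for s in samples])
        assert cv == pytest.approx(18.8, abs=2.0)

    def test_sample_time_out_of_range(self, default_trajectory):
        with pytest.raises(ValueError):
            generate_offline_reference(default_trajectory, [999.0], None, seed=0)


class TestRenderer:
    def test_empty_scene_is_background_only(self, optics):
        frame, anns = render_micrograph([], optics)
        assert anns == []
        assert frame.shape == (optics.frame_height, optics.frame_width)
        assert abs(float(frame.mean()) - optics.background_level) < 1.0
        assert float(frame.std()) < 2 * optics.background_noise_sd

    def test_focus_exclusion_rule(self, optics):
        rng = np.random.default_rng(0)
        cells = []
        for i in range(7):
            cells.append(CellSpec(1, 150 + 160 * i, 300, z=0.0, diameter=15.0,
                                  texture_seed=int(rng.integers(1 << 30))))
        for i in range(3):
            cells.append(CellSpec(1, 200 + 300 * i, 700,
                                  z=3 * optics.depth_of_field, diameter=15.0,
                                  texture_seed=int(rng.integers(1 << 30))))
        frame, anns = render_micrograph(cells, optics)
        assert len(anns) == 7

    def test_determinism_byte_identical(self, optics):
        cells = [CellSpec(3, 500, 500, z=0.0, diameter=15.0, texture_seed=99)]
        f1, a1 = render_micrograph(cells, optics)
        f2, a2 = render_micrograph(cells, optics)
        assert np.array_equal(f1, f2)
        assert a1 == a2

    def test_viable_interior_far_more_homogeneous_than_necrotic(self, optics):
        """Class-1 interior CoV is below class-3's by at least a factor 2."""
        cvs = {}
        for cls in (1, 3):
            vals = []
            for seed in range(3):
                frame, anns = single_cell_frame(cls, optics, seed=seed)
                (cid, box) = anns[0]
                cx = int(box.cx * optics.frame_width)
                cy = int(box.cy * optics.frame_height)
                r = int(min(box.w * optics.frame_width, box.h * optics.frame_height) / 4)
                yy, xx = np.mgrid[-r:r, -r:r]
                disc = (yy ** 2 + xx ** 2) < r ** 2
                patch = frame[cy - r:cy + r, cx - r:cx + r].astype(float)
                vals.append(patch[disc].std() / patch[disc].mean())
            cvs[cls] = np.mean(vals)
        assert cvs[1] * 2 <= cvs[3]

    def test_exposure_offset_signs(self, optics):
        bright, _ = render_micrograph(
            [CellSpec(1, 500, 500, z=2.5, diameter=15.0, texture_seed=4)], optics
        )
        dark, _ = render_micrograph(
            [CellSpec(1, 500, 500, z=-2.5, diameter=15.0, texture_seed=4)], optics
        )
        sl = (slice(470, 530), slice(470, 530))
        assert bright[sl].mean() > dark[sl].mean() + 5.0

    def test_invalid_diameter(self, optics):
        with pytest.raises(ValueError):
            render_micrograph([CellSpec(1, 100, 100, diameter=-5.0)], optics)
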
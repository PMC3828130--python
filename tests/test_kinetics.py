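"""Estimator correctness on synthetic series with known ground truth, bound
state detection, and the transport-rate algebra."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from patchybind.integrator import BoxSpec, Domain, SpeciesSpec, SystemState
from patchybind.kinetics import (
    ComplexTimeSeries,
    FitModel,
    RateEstimate,
    complex_timeseries,
    count_bound,
    detect_bound_pairs,
    equilibrium_occupancy,
    estimate_koff,
    estimate_kon_equilibrium,
    estimate_kon_short_time,
    rate_vs_diffusion,
    transport_decomposition,
)
from patchybind.potentials import (
    WCA_CUT_FACTOR,
    InteractionKind,
    InteractionSpec,
    angular_lj,
)
from patchybind.synthetic import (
    exponential_series,
    linear_series,
    markov_dissociation_series,
    mass_action_series,
    scripted_binding_frames,
)

LR = {("L", "R"): InteractionSpec(InteractionKind.ANGULAR_LJ, 5.0, 0.75,
                                  n_geom=0.0)}


def _two_species():
    return [
        SpeciesSpec("L", 0.5, 1.0, 0.1, Domain.BULK_3D),
        SpeciesSpec("R", 1.0, 2.0, 0.0, Domain.MEMBRANE_2D),
    ]


def _state(rec_pos, lig_pos, box=None):
    box = box or BoxSpec(12.0, 12.0, 10.0)
    rec = np.atleast_2d(rec_pos)
    lig = np.atleast_2d(lig_pos)
    pos = np.vstack([rec, lig])
    spidx = np.concatenate([
        np.full(len(rec), 1, dtype=np.int64), np.zeros(len(lig), dtype=np.int64)
    ])
    return SystemState(pos, np.zeros_like(pos), spidx, _two_species(), box)


class TestDetection:
    def test_ligand_at_minimum_is_bound(self):
        z = WCA_CUT_FACTOR * 0.75
        st = _state([[6, 6, 0]], [[6, 6, z]])
        assert detect_bound_pairs(st, LR) == {(1, 0)}

    def test_ligand_beyond_cutoff_not_bound(self):
        st = _state([[6, 6, 0]], [[6, 6, 3.0]])
        assert detect_bound_pairs(st, LR) == set()

    def test_threshold_fraction_validated(self):
        st = _state([[6, 6, 0]], [[6, 6, 3.0]])
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                detect_bound_pairs(st, LR, energy_threshold_fraction=bad)

    def test_one_ligand_two_receptors_single_assignment(self):
        # the ligand is inside the binding threshold of both receptors;
        # exhaustive energy evaluation picks the winner
        spec = LR[("L", "R")]
        rec = [[5.4, 6, 0], [6.6, 6, 0]]
        lig = [[5.95, 6, 0.65]]
        st = _state(rec, lig)
        energies = []
        for r in rec:
            u = np.array(lig[0]) - np.array(r)
            energies.append(angular_lj(u, [0, 0, 1.0], spec)[0])
        assert max(energies) < -0.5 * spec.epsilon  # both within threshold
        pairs = detect_bound_pairs(st, LR)
        assert len(pairs) == 1
        winner = int(np.argmin(energies))
        assert pairs == {(2, winner)}

    def test_two_ligands_one_receptor_single_assignment(self):
        z = WCA_CUT_FACTOR * 0.75
        st = _state([[6, 6, 0]], [[6, 6, z], [6.3, 6, z]])
        pairs = detect_bound_pairs(st, LR)
        assert pairs == {(1, 0)}  # on-axis ligand wins

    def test_scripted_frames_counts(self):
        schedule = [[0, 1, 2], [0, 2], [2], [], [1]]
        frames = scripted_binding_frames(schedule)
        series = complex_timeseries(frames, LR, pair=("L", "R"))
        np.testing.assert_array_equal(series.counts, [3, 2, 1, 0, 1])

    def test_static_bound_frames_constant(self):
        frames = scripted_binding_frames([[0, 1]] * 4)
        series = complex_timeseries(frames, LR)
        assert np.all(series.counts == 2)

    def test_empty_trajectory_is_error(self):
        with pytest.raises(ValueError):
            complex_timeseries([], LR)


class TestSeriesContainer:
    def test_validation(self):
        with pytest.raises(ValueError):
            ComplexTimeSeries([0.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ComplexTimeSeries([0.0, 1.0], [1.0, -1.0])

    def test_rate_estimate_validation(self):
        with pytest.raises(ValueError):
            RateEstimate(-1.0, 0.0, FitModel.EXP_DECAY, (0, 1), 1.0)


class TestKoff:
    def test_exact_recovery_noiseless(self):
        times = np.linspace(0, 80, 200)
        series = exponential_series(200.0, 0.05, times)
        est = estimate_koff(series)
        assert est.value == pytest.approx(0.05, abs=1e-6)
        assert est.gof > 0.999999

    def test_constant_series_gives_zero(self):
        series = ComplexTimeSeries(np.arange(10.0), np.full(10, 50.0))
        with pytest.warns(UserWarning, match="does not decay"):
            est = estimate_koff(series)
        assert est.value == 0.0

    def test_markov_ensemble_recovery(self):
        # parametric oracle: exact two-state Markov realisations
        rng = np.random.default_rng(1234)
        true = 0.05
        times = np.linspace(0, 60, 120)
        series = markov_dissociation_series(200, true, times, 20, rng)
        est = estimate_koff(series)
        assert abs(est.value - true) < max(2 * est.stderr, 0.1 * true)

    def test_all_zero_series_is_error(self):
        with pytest.raises(ValueError):
            estimate_koff(ComplexTimeSeries(np.arange(5.0), np.zeros(5)))

    def test_window_stops_at_noise_floor(self):
        times = np.linspace(0, 200, 400)
        series = exponential_series(100.0, 0.05, times)
        est = estimate_koff(series)
        # window closes when the mean count crosses 5 complexes
        assert est.fit_window[1] < times[-1]
        assert series.counts[np.searchsorted(times, est.fit_window[1])] <= 5.5


class TestKonShortTime:
    def test_exact_on_linear_series(self):
        times = np.linspace(0, 10, 50)
        kon_true, conc, n_r = 0.02, 1.0, 100.0
        series = linear_series(kon_true * conc * n_r, times)
        est = estimate_kon_short_time(series, conc, n_r)
        assert est.value == pytest.approx(kon_true, rel=1e-12)
        assert est.gof == pytest.approx(1.0)

    def test_zero_slope(self):
        series = linear_series(0.0, np.linspace(0, 10, 20))
        est = estimate_kon_short_time(series, 1.0, 100.0)
        assert est.value == 0.0

    def test_saturating_series_uses_short_window(self):
        kon_true, koff = 0.02, 0.05
        conc, n_r, vol = 0.5, 100.0, 1e6  # negligible depletion
        times = np.linspace(0, 400, 800)
        series = mass_action_series(kon_true, koff, conc, n_r, vol, times)
        est = estimate_kon_short_time(series, conc, n_r)
        assert est.value == pytest.approx(kon_true, rel=0.05)
        # the window must respect the 20% occupancy cap
        idx = np.searchsorted(times, est.fit_window[1])
        assert series.counts[idx] <= 0.21 * n_r

    def test_too_few_points_is_error(self):
        series = linear_series(10.0, np.linspace(0, 10, 40))
        with pytest.raises(ValueError):
            estimate_kon_short_time(series, 1.0, 10.0)  # cap hit immediately


class TestKonEquilibrium:
    def koff_est(self, value, stderr=0.0):
        return RateEstimate(value, stderr, FitModel.EXP_DECAY, (0, 1), 1.0)

    def test_half_occupancy_identity(self):
        # C_eq = N_R/2 with negligible depletion: kon = koff / [L]
        koff = 0.05
        conc, n_r, vol = 2.0, 100.0, 1e9
        times = np.linspace(0, 400, 400)
        counts = np.full(400, 50.0)
        counts[:50] = np.linspace(0, 50, 50)  # growth then plateau
        series = ComplexTimeSeries(times, counts)
        est = estimate_kon_equilibrium(series, self.koff_est(koff), conc, n_r, vol)
        assert est.value == pytest.approx(koff / conc, rel=1e-6)

    def test_ode_oracle_recovery(self):
        kon_true, koff = 0.03, 0.02
        conc, n_r, vol = 0.4, 100.0, 2000.0
        times = np.linspace(0, 1500, 600)
        series = mass_action_series(kon_true, koff, conc, n_r, vol, times)
        est = estimate_kon_equilibrium(series, self.koff_est(koff), conc, n_r, vol)
        assert est.value == pytest.approx(kon_true, rel=0.01)

    def test_zero_equilibrium_gives_zero(self):
        times = np.linspace(0, 100, 100)
        series = ComplexTimeSeries(times, np.zeros(100))
        est = estimate_kon_equilibrium(series, self.koff_est(0.1), 1.0, 10.0, 100.0)
        assert est.value == 0.0

    def test_no_plateau_is_error(self):
        times = np.linspace(0, 100, 200)
        series = ComplexTimeSeries(times, 0.5 * times)  # still growing
        with pytest.raises(ValueError, match="plateau"):
            estimate_kon_equilibrium(series, self.koff_est(0.1), 1.0, 100.0, 1e6)

    def test_agrees_with_short_time_on_same_ode(self):
        # the two estimators must coincide on a clean mass-action curve
        kon_true, koff = 0.025, 0.04
        conc, n_r, vol = 0.5, 200.0, 5000.0
        times = np.linspace(0, 800, 1600)
        series = mass_action_series(kon_true, koff, conc, n_r, vol, times)
        short = estimate_kon_short_time(series, conc, n_r)
        eq = estimate_kon_equilibrium(series, self.koff_est(koff), conc, n_r, vol)
        joint = math.hypot(short.stderr, eq.stderr) + 1e-12
        assert abs(short.value - eq.value) <= max(2 * joint, 0.05 * kon_true)


class TestDiffusionDependence:
    def est(self, v, se=0.0):
        return RateEstimate(v, se, FitModel.EXP_DECAY, (0, 1), 1.0)

    def test_exact_line(self):
        pts = [(d, self.est(3.0 * d + 0.5)) for d in (0.01, 0.02, 0.05, 0.1)]
        slope, intercept, r2 = rate_vs_diffusion(pts)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(0.5)
        assert r2 == pytest.approx(1.0)

    def test_constant_rates_zero_slope(self):
        pts = [(d, self.est(0.7)) for d in (0.01, 0.05, 0.1)]
        slope, _, _ = rate_vs_diffusion(pts)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_transport_composition_grid(self):
        # k_meas = k_int k_T/(k_int + k_T) with k_T = c D << k_int: slope ~ c
        c, k_int = 2.0, 50.0
        pts = []
        for d in (0.01, 0.02, 0.04, 0.08):
            kt = c * d
            pts.append((d, self.est(k_int * kt / (k_int + kt))))
        slope, _, r2 = rate_vs_diffusion(pts)
        assert slope == pytest.approx(c, rel=0.01)
        assert r2 > 0.999

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            rate_vs_diffusion([(0.1, self.est(1.0)), (0.2, self.est(2.0))])


class TestTransportDecomposition:
    def test_infinite_transport_is_identity(self):
        assert transport_decomposition(0.3, math.inf) == pytest.approx(0.3)

    def test_half_transport(self):
        # k_meas = k_T/2  =>  k_int = k_T
        assert transport_decomposition(0.5, 1.0) == pytest.approx(1.0)

    def test_diverges_toward_diffusion_limit(self):
        assert transport_decomposition(0.999, 1.0) > 500.0

    def test_always_at_least_measured(self):
        for km, kt in [(0.1, 0.5), (0.2, 0.21), (1e-3, 1.0)]:
            assert transport_decomposition(km, kt) >= km

    def test_unphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            transport_decomposition(1.0, 0.5)
        with pytest.raises(ValueError):
            transport_decomposition(0.0, 1.0)


class TestMarkovConsistency:
    def test_md_unbinding_times_follow_estimated_exponential(self):
        """Survival statistics of dynamics-simulation dissociation match a
        two-state Markov process with the fitted koff (KS, alpha=0.01)."""
        from patchybind.experiments import run_replicate
        from patchybind.system_setup import ExperimentSpec, Protocol
        from patchybind.integrator import Simulation
        from patchybind.system_setup import build_dissociation

        spec = ExperimentSpec(
            protocol=Protocol.DISSOCIATION, n_receptors=64, epsilon=4.0,
            n_geom=1.0, surface_density=0.003, box_height=20.0,
            n_steps=16000, sample_interval=100, n_replicates=1, seed=99,
        )
        state = build_dissociation(spec)
        inter = spec.interactions()
        sim = Simulation(state, inter, dt=spec.dt, seed=100)
        initial = detect_bound_pairs(state, inter)
        # escape time = last moment a pair is seen bound (brief threshold
        # flickers are not dissociation events)
        last_bound = dict.fromkeys(initial, 0.0)
        n_samples = spec.n_steps // spec.sample_interval
        for _ in range(n_samples):
            sim.run(spec.sample_interval, chunk=spec.sample_interval)
            bound = detect_bound_pairs(state, inter)
            for pair in initial:
                if pair in bound:
                    last_bound[pair] = state.time
        horizon = spec.n_steps * spec.dt
        escaped = {p: t for p, t in last_bound.items() if t < horizon - 1.0}
        # essentially every complex should have dissociated at eps = 4
        assert len(escaped) >= 0.95 * len(initial)
        dt_sample = spec.sample_interval * spec.dt
        times = np.array(sorted(escaped.values())) + 0.5 * dt_sample
        khat = 1.0 / times.mean()
        ks = stats.kstest(times, stats.expon(scale=1.0 / khat).cdf)
        assert ks.pvalue > 0.01
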
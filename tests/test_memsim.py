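"""Cascade simulator: initialization, stepping rules, traces and metrics."""

import numpy as np
import pytest
from scipy import stats

from memfluid import memsim
from memfluid.memsim import (
    R_FREE,
    T1,
    T2,
    T3,
    ConfigError,
    SimConfig,
    compare_fluidity,
    detect_oscillation,
    init,
    metrics,
    pairs_within,
    run,
    step,
)
from simutil import make_trace, tracer_msd_slope


def small_config(**kwargs):
    kwargs.setdefault("n_receptors", 20)
    kwargs.setdefault("n_scaffolds", 20)
    kwargs.setdefault("n_functionals", 20)
    kwargs.setdefault("n_inhibitors", 5)
    kwargs.setdefault("t_end", 0.05)
    return SimConfig(**kwargs)


class TestConfig:
    def test_invalid_config_lists_all_violations(self):
        with pytest.raises(ConfigError) as err:
            SimConfig(n_receptors=0, dt=-1.0)
        assert "n_receptors" in str(err.value)
        assert "dt" in str(err.value)

    def test_brownian_step_invariant_enforced(self):
        with pytest.raises(ConfigError, match="Brownian step"):
            SimConfig(d_normal=50.0, dt=0.01)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimConfig(n_receptors=42, fluidity_factor=2.0)
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimConfig.from_yaml(path) == cfg


class TestInit:
    def test_seeded_init_is_reproducible(self):
        a, b = init(small_config(seed=3)), init(small_config(seed=3))
        np.testing.assert_array_equal(a.r_pos, b.r_pos)
        np.testing.assert_array_equal(a.i_pos, b.i_pos)

    def test_all_particles_start_free_and_inactive(self):
        state = init(small_config(n_receptors=200))
        c = state.counts()
        assert c["R_free"] == 200 and c["T1"] == c["T2"] == c["T3"] == 0
        assert c["I_active"] == 0
        assert state.time == 0.0

    def test_positions_uniform_on_occupancy_grid(self):
        cfg = small_config(n_receptors=10_000)
        state = init(cfg)
        cells = (state.r_pos // (cfg.box_size / 4)).astype(int)
        counts = np.bincount(cells[:, 0] * 4 + cells[:, 1], minlength=16)
        assert stats.chisquare(counts).pvalue > 0.01


class TestPairsWithin:
    def test_grid_matches_brute_force_with_periodic_wrap(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (80, 2))
        b = rng.uniform(0, 1, (70, 2))
        # include points straddling the periodic boundary
        a[:10] = rng.uniform(0, 0.005, (10, 2))
        b[:10] = rng.uniform(0.995, 1.0, (10, 2))
        brute = pairs_within(a, b, 0.05, 1.0, method="bruteforce")
        grid = pairs_within(a, b, 0.05, 1.0, method="grid")
        np.testing.assert_array_equal(brute, grid)
        assert len(brute) > 0

    def test_periodic_metric_sees_across_boundary(self):
        a = np.array([[0.001, 0.5]])
        b = np.array([[0.999, 0.5]])
        assert len(pairs_within(a, b, 0.01, 1.0)) == 1


class TestStep:
    def test_frozen_distant_particles_only_activate(self):
        cfg = small_config(
            n_receptors=4, n_scaffolds=4, n_functionals=4, n_inhibitors=4,
            d_normal=0.0, p_ligand_on=0.5, on_windows=((0.0, 1.0),),
        )
        state = init(cfg)
        # spread everything far beyond the interaction radius
        grid = np.array([[0.1, 0.1], [0.1, 0.9], [0.9, 0.1], [0.9, 0.9]])
        state.r_pos = grid + 0.0
        state.s_pos = grid + 0.05
        state.f_pos = grid - 0.05
        state.i_pos = grid + np.array([0.05, -0.05])
        for _ in range(50):
            step(state, cfg)
        c = state.counts()
        assert c["T1"] > 0
        assert c["T2"] == c["T3"] == 0

    def test_adjacent_t1_and_scaffold_form_t2_in_one_step(self):
        cfg = small_config(
            n_receptors=1, n_scaffolds=1, n_functionals=1, n_inhibitors=1,
            d_normal=0.0, p_ligand_on=0.0, p_basal=0.0,
        )
        state = init(cfg)
        state.r_state[0] = T1
        state.r_pos[0] = [0.5, 0.5]
        state.s_pos[0] = [0.5, 0.505]
        state.f_pos[0] = [0.9, 0.9]
        state.i_pos[0] = [0.1, 0.1]
        step(state, cfg)
        assert state.r_state[0] == T2
        assert not state.s_free[0]

    def test_active_inhibitor_depolymerizes_t3_releasing_monomers(self):
        cfg = small_config(
            n_receptors=1, n_scaffolds=1, n_functionals=1, n_inhibitors=1,
            d_normal=0.0, p_ligand_on=0.0, p_basal=0.0, p_inhibitor_off=0.0,
        )
        state = init(cfg)
        state.r_state[0] = T3
        state.r_scaffold[0] = 0
        state.r_functional[0] = 0
        state.s_free[0] = False
        state.f_free[0] = False
        state.r_pos[0] = [0.5, 0.5]
        state.i_pos[0] = [0.5, 0.505]
        state.i_active[0] = True
        step(state, cfg)
        assert state.r_state[0] == R_FREE
        assert state.s_free[0] and state.f_free[0]
        # released monomers land within one interaction radius of the site
        for pos in (state.s_pos[0], state.f_pos[0]):
            assert np.linalg.norm(pos - [0.5, 0.5]) <= cfg.interaction_radius + 1e-12

    def test_conservation_holds_through_dense_reacting_run(self):
        cfg = SimConfig(
            n_receptors=50, n_scaffolds=50, n_functionals=50, n_inhibitors=20,
            box_size=0.3, on_windows=((0.0, 10.0),), k_feedback=1.0,
            p_inhibitor_off=0.05, t_end=0.04,
        )
        run(cfg, check_conservation=True)  # asserts invariants every step


class TestRun:
    def test_trace_is_deterministic_replay(self):
        cfg = small_config(seed=12)
        a, b = run(cfg), run(cfg)
        np.testing.assert_array_equal(a.output_signal, b.output_signal)
        np.testing.assert_array_equal(a.t3_frac, b.t3_frac)

    def test_neighbor_backends_give_identical_traces(self):
        cfg = small_config(seed=4, box_size=0.3, on_windows=((0.0, 10.0),))
        brute = run(cfg.replace(neighbor_method="bruteforce"))
        grid = run(cfg.replace(neighbor_method="grid"))
        np.testing.assert_array_equal(brute.output_signal, grid.output_signal)
        np.testing.assert_array_equal(brute.t3_frac, grid.t3_frac)

    def test_silent_system_stays_silent(self):
        cfg = small_config(p_basal=0.0, p_ligand_on=0.0)
        trace = run(cfg)
        assert np.all(trace.receptor_activation == 0)
        assert np.all(trace.output_signal == 0)

    def test_fluidity_factor_is_pure_diffusivity_multiplier(self):
        a = run(small_config(seed=6, d_normal=0.05, fluidity_factor=1.0))
        b = run(small_config(seed=6, d_normal=0.025, fluidity_factor=2.0))
        np.testing.assert_array_equal(a.t3_frac, b.t3_frac)
        np.testing.assert_array_equal(a.output_signal, b.output_signal)

    def test_fractions_bounded(self):
        cfg = SimConfig(t_end=0.15, seed=2)
        trace = run(cfg)
        for arr in (trace.t1_frac, trace.t2_frac, trace.t3_frac):
            assert np.all((arr >= 0) & (arr <= 1))
        np.testing.assert_allclose(
            trace.receptor_activation, trace.t1_frac + trace.t2_frac + trace.t3_frac
        )

    def test_every_t3_was_t2_on_the_previous_step(self):
        cfg = SimConfig(
            box_size=0.4, n_receptors=40, n_scaffolds=40, n_functionals=40,
            n_inhibitors=10, on_windows=((0.0, 10.0),), seed=7,
        )
        state = init(cfg)
        prev = state.r_state.copy()
        saw_t3 = False
        for _ in range(400):
            step(state, cfg)
            fresh = (state.r_state == T3) & (prev != T3)
            assert np.all(prev[fresh] == T2)
            saw_t3 |= bool(np.any(state.r_state == T3))
            prev = state.r_state.copy()
        assert saw_t3


class TestBrownianOracle:
    def test_tracer_msd_grows_as_4dt(self):
        slope, expected = tracer_msd_slope(n_particles=2000, n_steps=10_000, seed=1)
        assert slope == pytest.approx(expected, rel=0.05)


class TestMetrics:
    def test_linear_ramp_growth_rate_equals_slope(self):
        t = (np.arange(600) + 1) * 1e-3
        trace = make_trace(output_signal=0.1 * t)
        m = metrics(trace)
        assert m.max_growth_rate == pytest.approx(0.1, rel=1e-9)

    def test_pure_sine_t3_flags_oscillation_with_period(self):
        t = (np.arange(4500) + 1) * 1e-3
        trace = make_trace(
            t3_frac=0.2 + 0.1 * np.sin(2 * np.pi * t / 0.5),
            output_signal=np.zeros_like(t),
            config=SimConfig.resting(),
        )
        m = metrics(trace)
        assert m.oscillating
        assert m.period == pytest.approx(0.5, rel=0.05)

    def test_flat_trace_does_not_oscillate(self):
        flag, _ = detect_oscillation(np.full(1000, 0.3), 1e-3)
        assert not flag

    def test_saturating_trend_does_not_oscillate(self):
        t = np.arange(5000) * 1e-3
        flag, _ = detect_oscillation(1 - np.exp(-t / 1.5), 1e-3)
        assert not flag

    def test_short_trace_rejected(self):
        trace = make_trace(output_signal=np.zeros(5))
        with pytest.raises(ValueError, match="smoothing windows"):
            metrics(trace)


class TestFluidityEffect:
    def test_time_to_half_maximal_t3_nonincreasing_in_fluidity(self):
        factors = (0.5, 1.0, 2.0, 4.0)
        medians = []
        for factor in factors:
            times = []
            for s in range(6):
                cfg = SimConfig(t_end=0.25, fluidity_factor=factor, seed=300 + s)
                trace = run(cfg)
                after = trace.times >= 0.1
                y = trace.t3_frac[after]
                t = trace.times[after]
                half = np.flatnonzero(y >= 0.5 * y.max())
                times.append(t[half[0]] - 0.1)
            medians.append(np.median(times))
        assert all(a >= b - 1e-12 for a, b in zip(medians, medians[1:]))

    def test_compare_fluidity_with_unit_factor_gives_zero_differences(self):
        df, summary = compare_fluidity(
            small_config(t_end=0.3), n_seeds=2, fluidity_factor=1.0
        )
        assert np.allclose(
            df["superfluid_max_growth_rate"], df["normal_max_growth_rate"]
        )
        assert summary["p_growth_sign_test"] == 1.0

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError, match="n_seeds"):
            compare_fluidity(small_config(), n_seeds=1)
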
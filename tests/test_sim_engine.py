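import numpy as np
import pytest

from tempocode.sim_engine import (
    DEFAULT_COMPOUNDS,
    DEFAULT_LIGAND_SPECS,
    ConfigError,
    CoreModelParams,
    DrugRegime,
    LigandInputSpec,
    SimulationError,
    TimeGrid,
    apply_regime,
    build_dose_ladder,
    combination_regimes,
    default_model_params,
    find_steady_state,
    ikk_input_curve,
    input_function,
    make_regime,
    simulate_grid,
    simulate_regime,
    simulate_trajectory,
    single_drug_regimes,
)


class TestTimeGrid:
    def test_default_grid_is_481_points_at_1_min(self):
        grid = TimeGrid()
        assert grid.n_points == 481
        assert grid.dt == 1.0
        assert grid.span == 480.0
        assert grid.times[0] == 0.0 and grid.times[-1] == 480.0

    def test_rejects_degenerate_grids(self):
        with pytest.raises(ValueError):
            TimeGrid(n_points=1)
        with pytest.raises(ValueError):
            TimeGrid(dt=0)


class TestDoseLadder:
    def test_default_ladder_endpoints(self):
        ladder = build_dose_ladder(20, -0.15, -3)
        assert len(ladder) == 20
        assert ladder[-1] == pytest.approx(1e-3)
        # 10**-0.15 evaluated directly
        assert ladder[0] == pytest.approx(0.7079457843841379)

    def test_single_step_ladder(self):
        assert build_dose_ladder(1, -2, -2).tolist() == [pytest.approx(0.01)]

    def test_default_ladder_strictly_decreasing_in_unit_interval(self):
        ladder = build_dose_ladder()
        assert np.all(np.diff(ladder) < 0)
        assert np.all((ladder > 0) & (ladder < 1))

    def test_invalid_steps(self):
        with pytest.raises(ConfigError):
            build_dose_ladder(0, -0.15, -3)


class TestApplyRegime:
    def test_identity_regime(self, model_params):
        assert apply_regime(model_params, DrugRegime.untreated()) == model_params

    def test_full_dose_scales_all_targets(self, model_params, ladder):
        regime = make_regime("IKKi", 20, DEFAULT_COMPOUNDS["IKKi"], ladder)
        treated = apply_regime(model_params, regime)
        for name in DEFAULT_COMPOUNDS["IKKi"]:
            assert getattr(treated, name) == pytest.approx(
                getattr(model_params, name) * 1e-3
            )
        untouched = set(model_params.names()) - set(DEFAULT_COMPOUNDS["IKKi"])
        for name in untouched:
            assert getattr(treated, name) == getattr(model_params, name)

    def test_combination_composes_multiplicatively(self, model_params):
        a = DrugRegime("a", (("a", 1),), {"translation": 0.5})
        b = DrugRegime("b", (("b", 1),), {"translation": 0.5})
        combined = a.combine(b)
        treated = apply_regime(model_params, combined)
        assert treated.translation == pytest.approx(model_params.translation * 0.25)

    def test_unknown_parameter_is_config_error(self, model_params):
        bad = DrugRegime("bad", (("x", 1),), {"no_such_rate": 0.5})
        with pytest.raises(ConfigError, match="no_such_rate"):
            apply_regime(model_params, bad)


class TestInputCurve:
    def test_zero_amplitude_gives_zero_curve(self, reduced_grid):
        spec = LigandInputSpec("TNF", "Low", 0.0, 5.0, 60.0, 0.1)
        assert np.all(ikk_input_curve(spec, reduced_grid) == 0)

    def test_zero_at_onset_and_nonnegative(self, reduced_grid):
        for spec in DEFAULT_LIGAND_SPECS:
            curve = ikk_input_curve(spec, reduced_grid)
            assert curve[0] == 0.0
            assert np.all(curve >= 0)
            assert np.max(curve) <= spec.amplitude

    def test_full_plateau_curve_is_nondecreasing(self, default_grid_full):
        spec = LigandInputSpec("LPS", "High", 0.5, 20.0, 100.0, 1.0)
        curve = ikk_input_curve(spec, default_grid_full)
        assert np.all(np.diff(curve) >= 0)

    def test_amplitude_orders_curves_pointwise(self, reduced_grid):
        lo = LigandInputSpec("TNF", "Low", 0.3, 5.0, 60.0, 0.1)
        hi = LigandInputSpec("TNF", "High", 0.6, 5.0, 60.0, 0.1)
        c_lo = ikk_input_curve(lo, reduced_grid)
        c_hi = ikk_input_curve(hi, reduced_grid)
        assert np.all(c_hi >= c_lo)
        assert np.allclose(c_hi, 2.0 * c_lo)


class TestSimulateTrajectory:
    def test_zero_input_stays_at_baseline_below_cutoff(self, model_params, reduced_grid):
        values = simulate_trajectory(model_params, lambda t: 0.0, reduced_grid)
        assert np.max(values) < 0.05
        assert np.ptp(values) < 1e-6

    def test_conservation_within_tolerance(self, model_params, reduced_grid):
        spec = DEFAULT_LIGAND_SPECS[2]  # TNF high
        _, states = simulate_trajectory(
            model_params, input_function(spec, model_params), reduced_grid,
            return_states=True,
        )
        pools = states[2] + states[3] + states[4]
        assert np.max(np.abs(pools - model_params.nfkb_total)) < 1e-6
        assert np.all(states >= -1e-9)

    def test_phase1_steady_state_is_stationary(self, model_params):
        from tempocode.sim_engine.model import _rhs_factory, _zero_input

        y0 = find_steady_state(model_params)
        rhs = _rhs_factory(model_params, _zero_input)
        assert np.max(np.abs(rhs(0.0, y0))) < 1e-7

    def test_translation_block_enhances_late_activity(self, model_params, reduced_grid):
        # removing the negative feedback (translation x 1e-3) must raise
        # late-time activity under a step input
        step = lambda t: 0.5 * (np.asarray(t) >= 0)
        base = simulate_trajectory(model_params, step, reduced_grid)
        blocked = simulate_trajectory(
            model_params.with_updates(translation=model_params.translation * 1e-3),
            step, reduced_grid,
        )
        late = reduced_grid.times > 240
        assert blocked[late].mean() >= base[late].mean()

    def test_oracle_fine_grid_integration_agrees(self, model_params):
        # independent check: same equations integrated on a 10x finer output
        # grid agree with the standard call at the shared sample times
        coarse = TimeGrid(n_points=49, dt=10.0)
        fine = TimeGrid(n_points=481, dt=1.0)
        spec = DEFAULT_LIGAND_SPECS[1]
        u = input_function(spec, model_params)
        y0 = find_steady_state(model_params)
        a = simulate_trajectory(model_params, u, coarse, y0=y0)
        b = simulate_trajectory(model_params, u, fine, y0=y0)
        assert np.allclose(a, b[::10], atol=5e-5)

    def test_integration_failure_raises(self, reduced_grid):
        bad = CoreModelParams(translation=1e9, txn_induced=1e9)
        with pytest.raises(SimulationError):
            simulate_trajectory(bad, lambda t: 1.0, reduced_grid)


class TestSimulateGrid:
    def test_minimal_grid_single_cell(self, model_params, reduced_grid, ladder):
        regime = make_regime("CHX", 1, DEFAULT_COMPOUNDS["CHX"], ladder)
        tset = simulate_grid(
            model_params, [regime], DEFAULT_LIGAND_SPECS[:1], reduced_grid,
            include_untreated=False,
        )
        assert len(tset) == 1

    def test_combination_builder_yields_180_regimes(self, ladder):
        regimes = combination_regimes(DEFAULT_COMPOUNDS, ladder, (5, 10))
        assert len(regimes) == 180
        ids = {r.regime_id for r in regimes}
        assert len(ids) == 180

    def test_monotone_attenuation_for_pure_kinase_inhibitor(
        self, model_params, reduced_grid, ladder
    ):
        # TAK1i scales only the stimulus-driven kinase gain
        specs = DEFAULT_LIGAND_SPECS
        peaks = {}
        for dd in (1, 5, 9, 13, 17, 20):
            regime = make_regime("TAK1i", dd, DEFAULT_COMPOUNDS["TAK1i"], ladder)
            out = simulate_regime(model_params, regime, specs, reduced_grid)
            peaks[dd] = [out[s.label].values.max() for s in specs]
        dds = sorted(peaks)
        for i in range(len(dds) - 1):
            lo, hi = np.array(peaks[dds[i + 1]]), np.array(peaks[dds[i]])
            assert np.all(lo <= hi + 1e-9)

    def test_rerun_is_bit_identical(self, model_params, reduced_grid, ladder):
        regime = make_regime("Sel", 10, DEFAULT_COMPOUNDS["Sel"], ladder)
        a = simulate_regime(model_params, regime, DEFAULT_LIGAND_SPECS[:3], reduced_grid)
        b = simulate_regime(model_params, regime, DEFAULT_LIGAND_SPECS[:3], reduced_grid)
        for label in a:
            assert np.array_equal(a[label].values, b[label].values)

    def test_untreated_set_included(self, untreated_set):
        assert "untreated" in untreated_set.regime_ids
        assert len(untreated_set) == 15

    def test_untreated_taxonomy(self, untreated_set):
        # low-dose LPS is the designed complete non-responder
        lps_low = untreated_set.trajectories["untreated"]["LPS_L"]
        assert lps_low.values.max() < 0.05
        # high-dose CpG and Pam3CSK are near-coincident
        cpg = untreated_set.trajectories["untreated"]["CpG_H"].values
        pam = untreated_set.trajectories["untreated"]["Pam3CSK_H"].values
        assert np.max(np.abs(cpg - pam)) < 0.05
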
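import numpy as np
import pytest

from progdbn.dbn import CpdSet, DbnModel, DbnStructure
from progdbn.simulation import (
    SimulationConfig,
    TrajectorySet,
    impairment_curves,
    patient_density,
    simulate_cohort,
    simulate_patient,
    stratify_compare,
    survival_curve,
)
from progdbn.specs import (
    DEATH_NODE,
    TSO_NODE,
    Categorical,
    VariableSpec,
    cur_name,
    prev_name,
    unroll_nodes,
)



def single_var_model(p01: float, hazard, hazard_parent: bool = False) -> DbnModel:
    """One binary dynamic variable; optional state-dependent death hazard."""
    specs = [VariableSpec("x", "dynamic", 5, Categorical(("0", "1")))]
    nodes = unroll_nodes(specs)
    parents = {cur_name("x"): (prev_name("x"),)}
    tables = {
        cur_name("x"): np.array([[1 - p01, p01], [0.0, 1.0]]),
        TSO_NODE: np.full((1, 3), 1 / 3),
    }
    if hazard_parent:
        parents[DEATH_NODE] = (prev_name("x"),)
        tables[DEATH_NODE] = np.array([[1 - hazard[0], hazard[0]], [1 - hazard[1], hazard[1]]])
    else:
        parents[DEATH_NODE] = ()
        tables[DEATH_NODE] = np.array([[1 - hazard, hazard]])
    structure = DbnStructure(nodes=tuple(nodes), parents=parents)
    cards = {n.name: n.cardinality for n in nodes}
    cpds = CpdSet(tables=tables, parents=dict(structure.parents), cards=cards, alpha=0.0)
    return DbnModel(structure=structure, cpds=cpds, specs=specs, tso_cuts=(300.0, 550.0))


class TestSimulatePatient:
    def test_deterministic_model_single_trajectory(self):
        model = single_var_model(p01=1.0, hazard=0.0)
        cfg = SimulationConfig(n_slices=5, n_reps=20, seed=0)
        traj = simulate_patient(model, {"x": 0, "tso_days": 300.0}, cfg)
        # from x=0 the chain deterministically jumps to the absorbing 1
        for r in range(20):
            assert list(traj.states["x"][r]) == [0, 1, 1, 1, 1, 1]
        assert (traj.death_slice == -1).all()

    def test_certain_death_at_slice_one(self):
        model = single_var_model(p01=0.5, hazard=1.0)
        cfg = SimulationConfig(n_slices=10, n_reps=50, seed=0)
        traj = simulate_patient(model, {"x": 0, "tso_days": 100.0}, cfg)
        assert (traj.death_slice == 1).all()
        # no state is recorded after death
        assert (traj.states["x"][:, 1:] == -1).all()

    def test_two_state_chain_matches_closed_form(self):
        model = single_var_model(p01=0.1, hazard=0.0)
        cfg = SimulationConfig(n_slices=10, n_reps=10_000, seed=3)
        traj = simulate_patient(model, {"x": 0, "tso_days": 100.0}, cfg)
        for t in range(1, 11):
            p_emp = (traj.states["x"][:, t] == 1).mean()
            p_true = 1 - 0.9**t
            se = np.sqrt(p_true * (1 - p_true) / 10_000)
            assert abs(p_emp - p_true) <= 3 * max(se, 1e-4)

    def test_out_of_range_state_code_raises(self):
        model = single_var_model(p01=0.5, hazard=0.0)
        with pytest.raises(ValueError, match="cardinality"):
            simulate_patient(
                model, {"x": 7, "tso_days": 1.0}, SimulationConfig(n_reps=2, seed=0)
            )

    def test_missing_tso_raises(self):
        model = single_var_model(p01=0.5, hazard=0.0)
        with pytest.raises(ValueError, match="tso"):
            simulate_patient(model, {"x": 0}, SimulationConfig(n_reps=2, seed=0))


class TestSimulateCohort:
    def test_count_contract(self, small8_truth, small8_discrete):
        sub = small8_discrete.subset(small8_discrete.patient_ids[:10])
        cfg = SimulationConfig(n_slices=6, n_reps=400, seed=1)
        ts = simulate_cohort(small8_truth.model, sub, cfg)
        assert ts.n_trajectories == 10 * 400

    def test_seed_determinism(self, small8_truth, small8_discrete):
        sub = small8_discrete.subset(small8_discrete.patient_ids[:8])
        cfg = SimulationConfig(n_slices=8, n_reps=50, seed=9)
        a = simulate_cohort(small8_truth.model, sub, cfg)
        b = simulate_cohort(small8_truth.model, sub, cfg)
        for pid in a.patient_ids:
            assert (a.patients[pid].death_slice == b.patients[pid].death_slice).all()
            for k in a.patients[pid].event_slice:
                assert (
                    a.patients[pid].event_slice[k] == b.patients[pid].event_slice[k]
                ).all()

    def test_model_cohort_mismatch_raises(self, small8_truth, als_truth):
        from progdbn.synthetic import discretize_generated, generate_cohort

        c = generate_cohort(small8_truth, 20, seed=0)
        dc = discretize_generated(small8_truth, c)
        with pytest.raises(ValueError, match="lacks"):
            simulate_cohort(als_truth.model, dc, SimulationConfig(n_reps=2, seed=0))

    def test_mitos_monotone_and_absorption_invariants(self, small8_truth, small8_discrete):
        sub = small8_discrete.subset(small8_discrete.patient_ids[:20])
        cfg = SimulationConfig(n_slices=12, n_reps=30, seed=2)
        ts = simulate_cohort(small8_truth.model, sub, cfg, keep_states=True)
        for pt in ts.patients.values():
            st = pt.states["mitos_movement"]
            for r in range(pt.n_reps):
                row = st[r][st[r] != -1]
                assert (np.diff(row) >= 0).all()
                if pt.death_slice[r] >= 0:
                    assert (st[r][pt.death_slice[r]:] == -1).all()


class TestCurves:
    def _manual_trajset(self, event_slices, n_slices=10):
        from progdbn.simulation import OUTCOMES, PatientTrajectories

        cfg = SimulationConfig(n_slices=n_slices, n_reps=len(event_slices[0]), seed=0)
        patients = {}
        for i, ev in enumerate(event_slices):
            arr = np.asarray(ev)
            patients[f"p{i}"] = PatientTrajectories(
                patient_id=f"p{i}",
                death_slice=arr,
                event_slice={o: (arr if o == "death" else np.full_like(arr, -1)) for o in OUTCOMES},
                config=cfg,
            )
        return TrajectorySet(patients=patients, config=cfg, model_hash="x")

    def test_no_deaths_flat_zero(self):
        ts = self._manual_trajset([[-1, -1], [-1, -1]])
        curve = survival_curve(ts, [0, 3, 6])
        assert (curve["mean"] == 0).all()

    def test_all_dead_at_slice_one_steps_to_one(self):
        ts = self._manual_trajset([[1, 1], [1, 1]])
        curve = survival_curve(ts, [0, 1, 5])
        assert list(curve["mean"]) == [0.0, 1.0, 1.0]

    def test_curves_non_decreasing(self):
        ts = self._manual_trajset([[1, 4, -1], [2, -1, 9]])
        curve = survival_curve(ts, range(11))
        assert (np.diff(curve["mean"]) >= 0).all()

    def test_geometric_hazard_closed_form(self):
        model = single_var_model(p01=0.0, hazard=0.1)
        cfg = SimulationConfig(n_slices=10, n_reps=10_000, seed=5)
        traj = simulate_patient(model, {"x": 0, "tso_days": 50.0}, cfg, keep_states=False)
        ts = TrajectorySet(patients={"p": traj}, config=cfg, model_hash="x")
        curve = survival_curve(ts, range(1, 11))
        for t, mean in zip(curve["month"], curve["mean"]):
            p_true = 1 - 0.9**t
            se = np.sqrt(p_true * (1 - p_true) / 10_000)
            assert abs(mean - p_true) <= 3 * se

    def test_empty_trajset_raises(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError):
            survival_curve(TrajectorySet(patients={}, config=cfg, model_hash="x"), [1])


class TestPatientDensity:
    def test_rows_sum_to_one_and_match_chain_marginal(self):
        model = single_var_model(p01=0.1, hazard=0.0)
        cfg = SimulationConfig(n_slices=8, n_reps=10_000, seed=7)
        dens = patient_density(model, {"x": 0, "tso_days": 10.0}, cfg, ["x"])["x"]
        assert np.allclose(dens.sum(axis=1), 1.0, atol=1e-9)
        for t in range(9):
            assert abs(dens[t, 1] - (1 - 0.9**t)) < 0.02

    def test_deterministic_model_one_hot(self):
        model = single_var_model(p01=1.0, hazard=0.0)
        cfg = SimulationConfig(n_slices=4, n_reps=100, seed=0)
        dens = patient_density(model, {"x": 0, "tso_days": 10.0}, cfg, ["x"])["x"]
        assert dens[0, 0] == 1.0 and (dens[1:, 1] == 1.0).all()

    def test_unknown_variable_raises(self):
        model = single_var_model(p01=0.5, hazard=0.0)
        with pytest.raises(ValueError, match="unknown"):
            patient_density(model, {"x": 0, "tso_days": 1.0}, SimulationConfig(seed=0), ["y"])


class TestStratify:
    def test_identical_arms_zero_difference(self, small8_truth, small8_discrete):
        sub = small8_discrete.subset(small8_discrete.patient_ids[:15])
        cfg = SimulationConfig(n_slices=10, n_reps=40, seed=4)
        res = stratify_compare(
            small8_truth.model, sub, {"a": {"treatment": 1}, "b": {"treatment": 1}}, cfg
        )
        assert res["median_difference_months"] == 0.0
        sa = res["arms"]["a"]["survival"]["mean"]
        sb = res["arms"]["b"]["survival"]["mean"]
        assert (sa == sb).all()

    def test_variable_without_path_to_death_changes_nothing(
        self, small8_truth, small8_discrete
    ):
        # weight has no directed path to survival in the small preset
        sub = small8_discrete.subset(small8_discrete.patient_ids[:15])
        cfg = SimulationConfig(n_slices=10, n_reps=40, seed=4)
        res = stratify_compare(
            small8_truth.model, sub, {"lo": {"weight": 0}, "hi": {"weight": 2}}, cfg
        )
        sa = res["arms"]["lo"]["survival"]["mean"]
        sb = res["arms"]["hi"]["survival"]["mean"]
        assert (sa == sb).all()  # common random numbers make this exact

    def test_protective_treatment_extends_survival(self, small8_truth, small8_discrete):
        sub = small8_discrete.subset(small8_discrete.patient_ids[:60])
        cfg = SimulationConfig(n_slices=30, n_reps=60, seed=4)
        res = stratify_compare(
            small8_truth.model,
            sub,
            {"active": {"treatment": 1}, "placebo": {"treatment": 0}},
            cfg,
        )
        pa = res["arms"]["active"]["survival"]
        pp = res["arms"]["placebo"]["survival"]
        assert pa["mean"].iloc[-1] < pp["mean"].iloc[-1]

    def test_intervening_on_death_raises(self, small8_truth, small8_discrete):
        with pytest.raises(ValueError):
            stratify_compare(
                small8_truth.model,
                small8_discrete,
                {"a": {"death": 0}},
                SimulationConfig(n_reps=2, seed=0),
            )
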
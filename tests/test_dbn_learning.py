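import math

import numpy as np
import pandas as pd
import pytest

from progdbn.cohort import DiscreteCohort
from progdbn.dbn import (
    DbnStructure,
    FamilyScoreCache,
    LearnConfig,
    bic_score,
    build_transition_table,
    ci_test,
    dim_g,
    fit_dbn,
    full_skeleton,
    hill_climb,
    learn_parameters,
    mmpc,
)
from progdbn.specs import Categorical, ClinicalThresholds, VariableSpec

from helpers import best_bic_exhaustive, build_data, cur_mask


class TestCiTest:
    def test_deterministic_dependence(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 1000)
        data = build_data({"x": x, "y": x.copy()}, {"x": 2, "y": 2})
        _, p, dep = ci_test(data, "x", "y")
        assert dep and p < 1e-10

    def test_chain_blocked_by_conditioning(self):
        # x -> z -> y: strong links, conditioning on z separates x and y
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.integers(0, 2, n)
        z = np.where(rng.random(n) < 0.95, x, 1 - x)
        y = np.where(rng.random(n) < 0.95, z, 1 - z)
        data = build_data({"x": x, "y": y, "z": z}, {"x": 2, "y": 2, "z": 2})
        assert ci_test(data, "x", "y")[2]  # marginally dependent
        assert not ci_test(data, "x", "y", ("z",))[2]

    def test_null_type_one_error_calibrated(self):
        # independent fair coins: rejection rate at alpha 0.05 within [0.03, 0.07]
        rng = np.random.default_rng(2)
        n, reps = 400, 2000
        rejections = 0
        for _ in range(reps):
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            data = build_data({"x": x, "y": y}, {"x": 2, "y": 2})
            rejections += ci_test(data, "x", "y")[2]
        assert 0.03 <= rejections / reps <= 0.07

    def test_sparse_table_skipped_as_independent(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 30)
        data = build_data(
            {"x": x, "y": x.copy(), "z": rng.integers(0, 3, 30)},
            {"x": 3, "y": 3, "z": 3},
        )
        stat, p, dep = ci_test(data, "x", "y", ("z",))  # 27 cells, 30 rows
        assert (stat, p, dep) == (0.0, 1.0, False)

    def test_argument_validation(self):
        data = build_data({"x": np.zeros(10, dtype=int), "y": np.ones(10, dtype=int)}, {"x": 2, "y": 2})
        with pytest.raises(ValueError):
            ci_test(data, "x", "x")
        with pytest.raises(ValueError):
            ci_test(data, "x", "y", ("x",))


class TestMmpc:
    def test_independent_variables_empty_skeleton(self):
        rng = np.random.default_rng(4)
        n = 5000
        data = build_data(
            {v: rng.integers(0, 2, n) for v in "abc"}, {v: 2 for v in "abc"}
        )
        skel = mmpc(data, cur_mask({v: 2 for v in "abc"}))
        assert all(not s for s in skel.values())

    def test_chain_skeleton_without_shortcut(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.integers(0, 2, n)
        z = np.where(rng.random(n) < 0.9, x, 1 - x)
        y = np.where(rng.random(n) < 0.9, z, 1 - z)
        data = build_data({"x": x, "y": y, "z": z}, {"x": 2, "y": 2, "z": 2})
        skel = mmpc(data, cur_mask({"x": 2, "y": 2, "z": 2}))
        assert skel["x"] == {"z"} and skel["y"] == {"z"}
        assert skel["z"] == {"x", "y"}

    def test_mask_forbidden_pair_never_linked(self):
        # two slice t-1 nodes may not be adjacent no matter how correlated
        from progdbn.specs import LayerMask, NodeDef, Role

        rng = np.random.default_rng(6)
        n = 3000
        a = rng.integers(0, 2, n)
        nodes = [
            NodeDef("a[t-1]", Role.PREV, 2, base="a"),
            NodeDef("b[t-1]", Role.PREV, 2, base="b"),
            NodeDef("c[t]", Role.CUR, 2, base="c"),
        ]
        data = build_data(
            {"a[t-1]": a, "b[t-1]": a.copy(), "c[t]": rng.integers(0, 2, n)},
            {"a[t-1]": 2, "b[t-1]": 2, "c[t]": 2},
        )
        skel = mmpc(data, LayerMask(nodes))
        assert "b[t-1]" not in skel["a[t-1]"] and "a[t-1]" not in skel["b[t-1]"]


def _structure(cards: dict[str, int], parents: dict) -> DbnStructure:
    mask = cur_mask(cards)
    full = {n: tuple(parents.get(n, ())) for n in cards}
    return DbnStructure(nodes=mask.nodes, parents=full)


class TestBic:
    def test_dim_single_ternary_node(self):
        s = _structure({"a": 3}, {})
        assert dim_g(s) == 2

    def test_dim_chain(self):
        s = _structure({"a": 2, "b": 2, "c": 2}, {"b": ("a",), "c": ("b",)})
        assert dim_g(s) == 1 + 2 + 2

    def test_dim_two_parent_family(self):
        s = _structure({"a": 2, "b": 2, "c": 2}, {"c": ("a", "b")})
        assert dim_g(s) == 1 + 1 + (2 - 1) * 4

    def test_hand_computed_bic_single_binary_node(self):
        # M = 8, balanced: l = 8 ln 0.5, penalty = (ln 8)/2 * 1
        data = build_data({"a": np.array([0, 0, 0, 0, 1, 1, 1, 1])}, {"a": 2})
        s = _structure({"a": 2}, {})
        expected = 8 * math.log(0.5) - math.log(8) / 2
        assert bic_score(s, data) == pytest.approx(expected, abs=1e-12)
        assert bic_score(s, data) == pytest.approx(-6.5849, abs=1e-4)

    def test_edge_from_constant_node_lowers_score(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 100)
        const = np.zeros(100, dtype=int)
        data = build_data({"a": a, "k": const}, {"a": 2, "k": 2})
        without = bic_score(_structure({"a": 2, "k": 2}, {}), data)
        withedge = bic_score(_structure({"a": 2, "k": 2}, {"a": ("k",)}), data)
        assert withedge < without

    def test_family_decomposition_matches_joint_likelihood(self):
        # oracle: chain-rule product of family MLEs over each observed row
        rng = np.random.default_rng(8)
        n = 500
        a = rng.integers(0, 2, n)
        b = (a ^ (rng.random(n) < 0.3)).astype(int)
        c = (b ^ (rng.random(n) < 0.2)).astype(int)
        data = build_data({"a": a, "b": b, "c": c}, {"a": 2, "b": 2, "c": 2})
        s = _structure({"a": 2, "b": 2, "c": 2}, {"b": ("a",), "c": ("b",)})

        p_a = np.bincount(a, minlength=2) / n
        p_ba = np.zeros((2, 2))
        p_cb = np.zeros((2, 2))
        for pa in range(2):
            sel = a == pa
            p_ba[pa] = np.bincount(b[sel], minlength=2) / sel.sum()
            sel = b == pa
            p_cb[pa] = np.bincount(c[sel], minlength=2) / sel.sum()
        ll = sum(
            math.log(p_a[ai]) + math.log(p_ba[ai, bi]) + math.log(p_cb[bi, ci])
            for ai, bi, ci in zip(a, b, c)
        )
        expected = ll - math.log(n) / 2 * dim_g(s)
        assert bic_score(s, data) == pytest.approx(expected, rel=1e-10)

    def test_empty_data_raises(self):
        data = build_data({"a": np.array([], dtype=int)}, {"a": 2})
        with pytest.raises(ValueError):
            bic_score(_structure({"a": 2}, {}), data)


class TestHillClimb:
    def _vstructure_data(self, seed: int, n: int = 5000):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        noise = rng.random(n) < 0.1
        c = ((a & b) ^ noise).astype(int)
        return build_data({"a": a, "b": b, "c": c}, {"a": 2, "b": 2, "c": 2})

    def test_vstructure_reaches_enumeration_optimum(self):
        data = self._vstructure_data(seed=9)
        mask = cur_mask({"a": 2, "b": 2, "c": 2})
        structure, ledger = hill_climb(full_skeleton(mask), data, mask)
        assert bic_score(structure, data) == pytest.approx(
            best_bic_exhaustive(data, mask), rel=1e-12
        )

    def test_empty_skeleton_returns_empty_graph(self):
        data = self._vstructure_data(seed=10)
        mask = cur_mask({"a": 2, "b": 2, "c": 2})
        structure, ledger = hill_climb({n.name: set() for n in mask.nodes}, data, mask)
        assert structure.n_edges() == 0
        assert ledger.accepted_bics() == []

    def test_max_iter_zero_returns_initial(self):
        data = self._vstructure_data(seed=11)
        mask = cur_mask({"a": 2, "b": 2, "c": 2})
        structure, _ = hill_climb(full_skeleton(mask), data, mask, max_iter=0)
        assert structure.n_edges() == 0

    def test_ledger_bics_strictly_increase(self):
        data = self._vstructure_data(seed=12)
        mask = cur_mask({"a": 2, "b": 2, "c": 2})
        structure, ledger = hill_climb(full_skeleton(mask), data, mask)
        bics = ledger.accepted_bics()
        assert len(bics) >= 1
        assert all(b2 > b1 for b1, b2 in zip(bics, bics[1:]))
        empty = bic_score(_structure({"a": 2, "b": 2, "c": 2}, {}), data)
        assert bics[-1] >= empty


class TestParameters:
    def test_map_closed_form(self):
        # counts (3, 1), alpha=2 -> (4/6, 2/6)
        data = build_data({"a": np.array([0, 0, 0, 1])}, {"a": 2})
        s = _structure({"a": 2}, {})
        cpds = learn_parameters(s, data, alpha=2.0)
        assert cpds.tables["a"][0] == pytest.approx([4 / 6, 2 / 6])

    def test_unseen_parent_configuration_uniform(self):
        data = build_data(
            {"a": np.array([0, 0]), "b": np.array([0, 1])}, {"a": 2, "b": 2}
        )
        s = _structure({"a": 2, "b": 2}, {"b": ("a",)})
        cpds = learn_parameters(s, data, alpha=2.0)
        assert cpds.tables["b"][1] == pytest.approx([0.5, 0.5])  # a=1 never seen

    def test_alpha_one_is_maximum_likelihood(self):
        data = build_data({"a": np.array([0, 0, 0, 1])}, {"a": 2})
        s = _structure({"a": 2}, {})
        cpds = learn_parameters(s, data, alpha=1.0)
        assert cpds.tables["a"][0] == pytest.approx([0.75, 0.25])

    def test_rows_are_distributions_without_zeros(self):
        rng = np.random.default_rng(13)
        data = build_data(
            {"a": rng.integers(0, 3, 50), "b": rng.integers(0, 2, 50)},
            {"a": 3, "b": 2},
        )
        s = _structure({"a": 3, "b": 2}, {"b": ("a",)})
        cpds = learn_parameters(s, data, alpha=2.0)
        for tab in cpds.tables.values():
            assert (tab > 0).all()
            assert np.allclose(tab.sum(axis=1), 1.0)


class TestFitDbn:
    def test_refit_identical(self, small8_discrete):
        m1 = fit_dbn(small8_discrete, LearnConfig())
        m2 = fit_dbn(small8_discrete, LearnConfig())
        assert m1.structure.parents == m2.structure.parents
        assert m1.model_hash() == m2.model_hash()

    def test_constant_cohort_yields_empty_graph(self):
        pids = [f"p{i}" for i in range(30)]
        statics = pd.DataFrame({"treatment": 0}, index=pd.Index(pids, name="patient_id"))
        rows = []
        for pid in pids:
            for day in (0, 40, 80):
                rows.append((pid, day, 1, 1, 500.0 + day))
        visits = pd.DataFrame(rows, columns=["patient_id", "day_offset", "fvc", "tso", "tso_raw"])
        visits["tso"] = 1
        dc = DiscreteCohort(
            statics=statics,
            visits=visits,
            death_day=pd.Series(np.nan, index=statics.index),
            specs=[
                VariableSpec("treatment", "static", 3, Categorical(("a", "b"))),
                VariableSpec("fvc", "dynamic", 5, ClinicalThresholds((50.0, 80.0))),
            ],
            tso_cuts=(300.0, 550.0),
        )
        model = fit_dbn(dc)
        assert model.structure.n_edges() == 0

    def test_learned_structure_respects_mask_and_acyclicity(self, small8_discrete):
        model = fit_dbn(small8_discrete)
        data, nodes, mask = build_transition_table(small8_discrete)
        model.structure.validate_mask(mask)  # raises on violation
        assert model.structure.is_acyclic()
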
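import dataclasses
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pathbn
from pathbn.cgbn import GaussianLocal, NetworkStructure, CGParameters
from pathbn.learn import build_constraints
from pathbn.synthetic import (
    AVAILABILITY,
    GroundTruthSpec,
    StudyDesign,
    apply_missingness,
    build_default_truth,
    demo_truth,
    random_truth,
    simulate_cohort,
    spec_from_json,
    spec_to_json,
)
from pathbn.variables import Continuous, VariableSpec


@pytest.fixture(scope="module")
def default_spec():
    return build_default_truth(0)


class TestDefaultTruth:
    def test_deterministic_for_fixed_seed(self, default_spec):
        assert spec_to_json(build_default_truth(0)) == spec_to_json(default_spec)

    def test_satisfies_all_constraints(self, default_spec):
        cs = build_constraints(default_spec.variables)
        cs.validate(default_spec.true_dag)
        tiers = {v.name: v.tier_index for v in default_spec.variables}
        for u, v in default_spec.true_dag.arcs:
            tu, tv = tiers[u], tiers[v]
            assert tu is None or tv is None or tu <= tv

    def test_intervention_parents_restricted_to_baseline_world(self, default_spec):
        roles = {v.name: v.role for v in default_spec.variables}
        parents = default_spec.true_dag.parents("intervention")
        assert all(roles[p] in ("demographic", "baseline") for p in parents)

    def test_mediated_paths_reach_both_outcomes(self, default_spec):
        g = default_spec.true_dag.to_networkx()
        for target in ("pa@T2", "pa@T3"):
            paths = list(nx.all_simple_paths(g, "intervention", target, cutoff=6))
            assert any(len(p) >= 3 for p in paths)  # at least one mediated route

    def test_inventory_follows_availability_table(self, default_spec):
        names = {v.name for v in default_spec.variables}
        for concept, tiers in AVAILABILITY.items():
            for tier in tiers:
                assert f"{concept}@{tier}" in names
        assert "intrinsic_motivation@T3" not in names  # never measured at T3
        assert "habit@T1" not in names

    def test_designs_never_mask_demographics_or_intervention(self, default_spec):
        for d in default_spec.study_designs:
            for name in ("age", "gender", "education", "intervention"):
                assert name in d.measured


class TestSimulateCohort:
    def test_root_mean_within_three_standard_errors(self, default_spec):
        table = simulate_cohort(default_spec, 5000, 1)
        se = 9.32 / math.sqrt(5000)
        assert abs(table["age"].mean() - 65.0) < 3 * se

    def test_single_record_complete(self, default_spec):
        table = simulate_cohort(default_spec, 1, 7)
        assert len(table) == 1
        assert table.notna().all().all()

    def test_reproducible(self, default_spec):
        a = simulate_cohort(default_spec, 100, 3)
        b = simulate_cohort(default_spec, 100, 3)
        pd.testing.assert_frame_equal(a, b)

    def test_deterministic_arc_copies_column(self):
        vs = [VariableSpec("X", "x", "T1", Continuous(), "determinant"),
              VariableSpec("Y", "y", "T2", Continuous(), "determinant")]
        params = CGParameters({
            "X": GaussianLocal((), (), (), np.array([0.0]), np.zeros((1, 0)),
                               np.array([1.0])),
            "Y": GaussianLocal((), (), ("X",), np.array([0.0]),
                               np.array([[1.0]]), np.array([0.0]))})
        spec = GroundTruthSpec(
            variables=vs,
            true_dag=NetworkStructure(["X", "Y"], [("X", "Y")]),
            parameters=params,
            study_designs=[StudyDesign("s", 1, {"X", "Y"})])
        table = simulate_cohort(spec, 50, 2)
        np.testing.assert_allclose(table["X"], table["Y"])

    def test_arc_free_roots_uncorrelated(self, default_spec):
        table = simulate_cohort(default_spec, 10000, 5)
        # attitude@T0 and social_modelling@T0 are independent roots
        assert ("attitude@T0" not in default_spec.true_dag.parents("social_modelling@T0"))
        r = np.corrcoef(table["attitude@T0"], table["social_modelling@T0"])[0, 1]
        assert abs(r) < 0.05

    def test_scales_respect_declared_ranges(self, default_spec):
        table = simulate_cohort(default_spec, 2000, 9)
        assert table["intention@T2"].between(1, 10).all()
        assert table["habit@T2"].between(1, 5).all()
        assert (table["pa@T2"] >= 0).all()

    def test_incomplete_parameters_rejected(self, default_spec):
        broken = dataclasses.replace(default_spec)
        broken.parameters = CGParameters(dict(default_spec.parameters.locals))
        del broken.parameters.locals["pa@T2"]
        with pytest.raises(ValueError, match="incomplete"):
            simulate_cohort(broken, 10, 0)


class TestApplyMissingness:
    def test_design_blocks_masked(self, default_spec):
        table = simulate_cohort(default_spec, 2000, 2)
        masked = apply_missingness(table, default_spec, 3)
        s3 = masked[masked.study_id == "study3"]
        assert s3["habit@T0"].isna().all()      # study 3 never measured habit at T0
        assert s3["pa@T3"].isna().all()         # study 3 had no 12-month wave
        s1 = masked[masked.study_id == "study1"]
        assert s1["habit@T0"].notna().any()

    def test_zero_rate_full_design_is_identity(self, default_spec):
        spec = dataclasses.replace(default_spec, extra_missing_rate=0.0)
        all_vars = {v.name for v in spec.variables}
        spec.study_designs = [StudyDesign(d.study_id, d.n_participants, set(all_vars))
                              for d in spec.study_designs]
        table = simulate_cohort(spec, 200, 4)
        masked = apply_missingness(table, spec, 5)
        pd.testing.assert_frame_equal(masked, table)

    def test_extra_mcar_rate_calibrated(self, default_spec):
        spec = dataclasses.replace(default_spec, extra_missing_rate=0.2)
        all_vars = {v.name for v in spec.variables}
        spec.study_designs = [StudyDesign(d.study_id, d.n_participants, set(all_vars))
                              for d in spec.study_designs]
        table = simulate_cohort(spec, 10000, 6)
        masked = apply_missingness(table, spec, 7)
        eligible = [v.name for v in spec.variables
                    if v.role not in ("demographic", "intervention")]
        frac = masked[eligible].isna().to_numpy().mean()
        assert abs(frac - 0.2) < 0.01

    def test_demographics_and_intervention_never_masked(self, default_spec):
        table = simulate_cohort(default_spec, 1000, 8)
        masked = apply_missingness(table, default_spec, 9)
        for name in ("age", "gender", "education", "intervention"):
            assert masked[name].notna().all()

    def test_unknown_study_rejected(self, default_spec):
        table = simulate_cohort(default_spec, 10, 1)
        table.loc[0, "study_id"] = "nope"
        with pytest.raises(ValueError, match="unknown study"):
            apply_missingness(table, default_spec, 0)


class TestSerialisationAndRandomTruths:
    def test_spec_json_round_trip(self, default_spec):
        back = spec_from_json(spec_to_json(default_spec))
        assert spec_to_json(back) == spec_to_json(default_spec)

    def test_random_truths_are_legal(self):
        for seed in range(10):
            spec = random_truth(seed)
            spec.validate()

    def test_demo_truth_designs_differ(self):
        spec = demo_truth()
        measured = [d.measured for d in spec.study_designs]
        assert measured[0] != measured[1]
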
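import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathbn.cgbn import (
    BICScorer,
    CGParameters,
    GaussianLocal,
    NetworkStructure,
    bic_score,
    fit_parameters,
    impute_record,
    impute_table,
    log_likelihood,
    params_from_json,
    params_to_json,
    sample,
    structure_from_dot,
    structure_to_dot,
)
from pathbn.variables import Continuous, Discrete, VariableSpec


def V(name, tier="T1", discrete=None, role=None):
    if discrete:
        vtype = Discrete(tuple(discrete))
    else:
        vtype = Continuous()
    if role is None:
        role = "determinant" if tier in ("T1", "T2", "T3") else "baseline"
    return VariableSpec(name, name.lower(), tier, vtype, role)


class TestStructure:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            NetworkStructure(["a", "b"], [("a", "b"), ("b", "a")])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            NetworkStructure(["a"], [("a", "a")])

    def test_dot_round_trip(self):
        g = NetworkStructure(["a", "b", "c"], [("a", "b"), ("b", "c")])
        back = structure_from_dot(structure_to_dot(g))
        assert back.nodes == g.nodes and back.arcs == g.arcs


class TestFitParameters:
    def test_binary_empirical_frequency(self):
        vs = [V("X", discrete=(0, 1))]
        data = pd.DataFrame({"X": [1, 1, 0, 1]})
        params = fit_parameters(NetworkStructure(["X"]), data, vs, pseudo_count=0)
        np.testing.assert_allclose(params["X"].cpt[0], [0.25, 0.75])

    def test_exact_linear_dependence(self):
        vs = [V("X"), V("Y", "T2")]
        x = np.linspace(-2, 2, 50)
        data = pd.DataFrame({"X": x, "Y": 2 * x})
        params = fit_parameters(NetworkStructure(["X", "Y"], [("X", "Y")]), data, vs)
        loc = params["Y"]
        assert loc.coef[0, 0] == pytest.approx(2.0, abs=1e-10)
        assert loc.var[0] == pytest.approx(0.0, abs=1e-10)

    def test_regression_recovery_within_three_se(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        vs = [V("X"), V("Y", "T2")]
        data = pd.DataFrame({"X": x, "Y": y})
        loc = fit_parameters(NetworkStructure(["X", "Y"], [("X", "Y")]), data, vs)["Y"]
        se = 1 / math.sqrt(n)
        assert abs(loc.b0[0] - 1.0) < 3 * se
        assert abs(loc.coef[0, 0] - 0.5) < 3 * se

    def test_insufficient_observations_raise(self):
        vs = [V("G", discrete=(0, 1)), V("Y", "T2")]
        data = pd.DataFrame({"G": [0, 0, 0, 1], "Y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            fit_parameters(NetworkStructure(["G", "Y"], [("G", "Y")]), data, vs)
        # pooled fallback keeps going
        fit_parameters(NetworkStructure(["G", "Y"], [("G", "Y")]), data, vs,
                       on_insufficient="pool")


class TestLogLikelihood:
    def test_fair_coin_closed_form(self):
        vs = [V("X", discrete=(0, 1))]
        params = fit_parameters(NetworkStructure(["X"]),
                                pd.DataFrame({"X": [0, 1]}), vs, pseudo_count=0)
        data = pd.DataFrame({"X": [0, 1, 0, 1]})
        assert log_likelihood(params, data, vs) == pytest.approx(4 * math.log(0.5))

    def test_standard_normal_at_mean(self):
        vs = [V("X")]
        params = CGParameters({"X": GaussianLocal((), (), (), np.array([0.0]),
                                                  np.zeros((1, 0)), np.array([1.0]))})
        out = log_likelihood(params, pd.DataFrame({"X": [0.0]}), vs)
        assert out == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_joint_density_oracle(self):
        # X -> Y linear-Gaussian chain: compare with the bivariate normal pdf
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        y = 0.7 * x + 0.5 * rng.standard_normal(200)
        vs = [V("X"), V("Y", "T2")]
        data = pd.DataFrame({"X": x, "Y": y})
        g = NetworkStructure(["X", "Y"], [("X", "Y")])
        params = fit_parameters(g, data, vs)
        ll = log_likelihood(params, data, vs)
        b0, b1 = params["Y"].b0[0], params["Y"].coef[0, 0]
        vx = params["X"].var[0]
        vy = params["Y"].var[0]
        mean = [params["X"].b0[0], b0 + b1 * params["X"].b0[0]]
        cov = [[vx, b1 * vx], [b1 * vx, vy + b1 ** 2 * vx]]
        oracle = stats.multivariate_normal(mean, cov).logpdf(np.column_stack([x, y])).sum()
        assert ll == pytest.approx(oracle, rel=1e-9)

    def test_zero_probability_observation_raises(self):
        vs = [V("X", discrete=(0, 1))]
        params = fit_parameters(NetworkStructure(["X"]),
                                pd.DataFrame({"X": [0, 0]}), vs, pseudo_count=0)
        with pytest.raises(ValueError, match="zero-probability"):
            log_likelihood(params, pd.DataFrame({"X": [1]}), vs)


class TestBIC:
    def test_binary_root_closed_form(self):
        vs = [V("X", discrete=(0, 1))]
        data = pd.DataFrame({"X": [1] * 60 + [0] * 40})
        expected = 60 * math.log(0.6) + 40 * math.log(0.4) - 0.5 * math.log(100)
        assert bic_score(NetworkStructure(["X"]), data, vs) == pytest.approx(expected)

    def test_decomposes_into_local_scores(self):
        rng = np.random.default_rng(0)
        vs = [V("A"), V("B"), V("C", "T2"), V("D", "T2")]
        data = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("ABCD"))
        scorer = BICScorer(data, vs)
        for arcs in ([], [("A", "C")], [("A", "C"), ("B", "C"), ("C", "D")]):
            g = NetworkStructure(list("ABCD"), arcs)
            total = bic_score(g, data, vs)
            local_sum = sum(scorer.local(n, g.parents(n)) for n in g.nodes)
            assert total == pytest.approx(local_sum)

    def test_true_arc_beats_empty_graph(self, compact_spec):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        y = 1.2 * x + rng.standard_normal(2000)
        vs = [V("X"), V("Y", "T2")]
        data = pd.DataFrame({"X": x, "Y": y})
        assert (bic_score(NetworkStructure(["X", "Y"], [("X", "Y")]), data, vs)
                > bic_score(NetworkStructure(["X", "Y"]), data, vs))

    def test_invariant_to_record_and_variable_order(self):
        rng = np.random.default_rng(1)
        vs = [V("A"), V("B", "T2")]
        data = pd.DataFrame({"A": rng.standard_normal(100),
                             "B": rng.standard_normal(100)})
        g = NetworkStructure(["A", "B"], [("A", "B")])
        s1 = bic_score(g, data, vs)
        s2 = bic_score(g, data.iloc[::-1].reset_index(drop=True), vs)
        s3 = bic_score(g, data[["B", "A"]], vs)
        assert s1 == pytest.approx(s2) == pytest.approx(s3)

    def test_ml_fit_maximises_likelihood(self):
        rng = np.random.default_rng(2)
        vs = [V("X")]
        data = pd.DataFrame({"X": rng.standard_normal(500)})
        g = NetworkStructure(["X"])
        params = fit_parameters(g, data, vs)
        best = log_likelihood(params, data, vs)
        for _ in range(10):
            perturbed = CGParameters({"X": GaussianLocal(
                (), (), (),
                params["X"].b0 + rng.normal(0, 0.2),
                np.zeros((1, 0)),
                params["X"].var * float(rng.uniform(0.6, 1.6)))})
            assert log_likelihood(perturbed, data, vs) <= best + 1e-9


class TestSample:
    def test_empty_and_deterministic(self, compact_spec):
        g, p, vs = compact_spec.true_dag, compact_spec.parameters, compact_spec.variables
        assert len(sample(g, p, vs, 0, seed=1)) == 0
        a = sample(g, p, vs, 50, seed=9)
        b = sample(g, p, vs, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_independent_roots_uncorrelated(self):
        vs = [V("A"), V("B")]
        p = CGParameters({
            "A": GaussianLocal((), (), (), np.array([0.0]), np.zeros((1, 0)),
                               np.array([1.0])),
            "B": GaussianLocal((), (), (), np.array([0.0]), np.zeros((1, 0)),
                               np.array([1.0]))})
        out = sample(NetworkStructure(["A", "B"]), p, vs, 10000, seed=4)
        assert abs(np.corrcoef(out["A"], out["B"])[0, 1]) < 0.05

    def test_sample_then_fit_recovers_parameters(self, compact_spec):
        data = sample(compact_spec.true_dag, compact_spec.parameters,
                      compact_spec.variables, 5000, seed=21)
        params = fit_parameters(compact_spec.true_dag, data, compact_spec.variables,
                                on_insufficient="pool")
        loc_true = compact_spec.parameters["intention@T2"]
        loc_fit = params["intention@T2"]
        n = 5000
        for j in range(loc_true.coef.shape[1]):
            se = math.sqrt(loc_true.var[0]) / (math.sqrt(n) * 0.4)  # conservative
            assert abs(loc_fit.coef[0, j] - loc_true.coef[0, j]) < 3 * se


class TestImpute:
    def _chain(self, coef=2.0, noise=0.0):
        vs = [V("X"), V("Y", "T2")]
        g = NetworkStructure(["X", "Y"], [("X", "Y")])
        p = CGParameters({
            "X": GaussianLocal((), (), (), np.array([0.0]), np.zeros((1, 0)),
                               np.array([1.0])),
            "Y": GaussianLocal((), (), ("X",), np.array([0.0]),
                               np.array([[coef]]), np.array([noise]))})
        return g, p, vs

    def test_fully_observed_unchanged(self):
        g, p, vs = self._chain()
        rec = impute_record(g, p, vs, {"X": 1.0, "Y": 2.5})
        assert rec == {"X": 1.0, "Y": 2.5}

    def test_deterministic_conditional(self):
        g, p, vs = self._chain(coef=2.0, noise=0.0)
        rec = impute_record(g, p, vs, {"X": 3.0, "Y": float("nan")})
        assert rec["Y"] == pytest.approx(6.0, abs=1e-6)

    def test_bivariate_normal_conditional_mean(self):
        # X ~ N(0,1), Y = 0.6X + e; impute X from Y: E[X|y] = rho*sx/sy*y
        g, p, vs = self._chain(coef=0.6, noise=0.64)
        rec = impute_record(g, p, vs, {"X": float("nan"), "Y": 1.5})
        assert rec["X"] == pytest.approx(0.6 * 1.5, abs=1e-6)

    def test_fully_missing_gets_marginals(self):
        g, p, vs = self._chain(coef=0.6, noise=0.64)
        rec = impute_record(g, p, vs, {"X": float("nan"), "Y": float("nan")})
        assert rec["X"] == pytest.approx(0.0, abs=1e-9)
        assert rec["Y"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_discrete_cell_restored(self):
        vs = [V("G", discrete=(0, 1)), V("Y", "T2")]
        g = NetworkStructure(["G", "Y"], [("G", "Y")])
        p = CGParameters({
            "G": __import__("pathbn.cgbn", fromlist=["DiscreteLocal"]).DiscreteLocal(
                levels=(0, 1), parents=(), plevels=(),
                cpt=np.array([[0.5, 0.5]])),
            "Y": GaussianLocal(("G",), (2,), (), np.array([0.0, 10.0]),
                               np.zeros((2, 0)), np.array([1.0, 1.0]))})
        rec = impute_record(g, p, vs, {"G": None, "Y": 9.7})
        assert rec["G"] == 1

    def test_draw_mode_reproducible(self):
        g, p, vs = self._chain(coef=0.6, noise=0.64)
        table = pd.DataFrame({"X": [np.nan, 1.0], "Y": [0.5, np.nan]})
        a = impute_table(g, p, vs, table, mode="draw", seed=3)
        b = impute_table(g, p, vs, table, mode="draw", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestObservedLikelihood:
    def test_reduces_to_complete_data_likelihood(self, compact_spec):
        from pathbn.cgbn import observed_log_likelihood
        data = sample(compact_spec.true_dag, compact_spec.parameters,
                      compact_spec.variables, 50, seed=13)
        full = log_likelihood(compact_spec.parameters, data, compact_spec.variables)
        marg = observed_log_likelihood(compact_spec.true_dag,
                                       compact_spec.parameters,
                                       compact_spec.variables, data)
        assert marg == pytest.approx(full, rel=1e-9)

    def test_marginalises_missing_cell_exactly(self):
        from pathbn.cgbn import observed_log_likelihood
        vs = [V("X"), V("Y", "T2")]
        g = NetworkStructure(["X", "Y"], [("X", "Y")])
        p = CGParameters({
            "X": GaussianLocal((), (), (), np.array([0.0]), np.zeros((1, 0)),
                               np.array([1.0])),
            "Y": GaussianLocal((), (), ("X",), np.array([0.0]),
                               np.array([[0.6]]), np.array([0.64]))})
        table = pd.DataFrame({"X": [1.0], "Y": [np.nan]})
        out = observed_log_likelihood(g, p, vs, table)
        assert out == pytest.approx(-0.5 * (math.log(2 * math.pi) + 1.0), abs=1e-6)


class TestSerialisation:
    def test_params_json_round_trip(self, compact_spec):
        text = params_to_json(compact_spec.parameters)
        back = params_from_json(text)
        for node, loc in compact_spec.parameters.locals.items():
            other = back.locals[node]
            if isinstance(loc, GaussianLocal):
                np.testing.assert_allclose(loc.b0, other.b0, atol=1e-12)
                np.testing.assert_allclose(loc.coef, other.coef, atol=1e-12)
                np.testing.assert_allclose(loc.var, other.var, atol=1e-12)
            else:
                np.testing.assert_allclose(loc.cpt, other.cpt, atol=1e-12)
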
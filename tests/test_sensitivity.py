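"""Local sensitivities, Morris screening, covariance and subset selection.

These use cheap algebraic residual functions with known structure; the
forward-model pipeline is exercised in the integration tests.
"""

import math

import numpy as np
import pytest

from pulsetree.sensitivity import (
    SAConfig,
    correlation_analysis,
    local_sensitivity,
    morris_screening,
    morris_step,
    select_subset,
)


def linear_residual(B, names):
    """r(theta) = B @ theta_tilde with theta_tilde = log|theta| (so the
    centred difference is exact)."""

    def fn(theta):
        x = np.array([math.log(abs(theta[n])) for n in names])
        return B @ x

    return fn


class TestLocalSensitivity:
    def test_linear_map_recovered_exactly(self):
        rng = np.random.default_rng(0)
        names = ("a", "b", "c")
        B = rng.standard_normal((6, 3))
        res = local_sensitivity(linear_residual(B, names), dict(a=1.0, b=2.0, c=0.5))
        assert np.allclose(res.S, B, atol=1e-9)
        assert np.allclose(res.S_bar, np.linalg.norm(B, axis=0), atol=1e-9)

    def test_centred_difference_is_second_order(self):
        # residual sin(theta_tilde): halving psi shrinks the error ~4x
        def fn(theta):
            return np.array([math.sin(math.log(theta["a"]))])

        errs = []
        for psi in (0.2, 0.1):
            res = local_sensitivity(fn, {"a": math.e}, SAConfig(psi=psi))
            errs.append(abs(res.S[0, 0] - math.cos(1.0)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)

    def test_duplicate_parameters_have_identical_columns(self):
        def fn(theta):
            s = math.log(theta["a"]) + math.log(theta["b"])
            return np.array([s, 2 * s])

        res = local_sensitivity(fn, {"a": 1.5, "b": 1.5})
        assert np.allclose(res.S[:, 0], res.S[:, 1])
        assert res.S_bar[0] == pytest.approx(res.S_bar[1])

    def test_one_sided_fallback_on_failure(self):
        def fn(theta):
            if theta["a"] > 2.0:
                raise RuntimeError("forward model diverged")
            return np.array([math.log(theta["a"])])

        res = local_sensitivity(fn, {"a": 2.0}, SAConfig(psi=0.01))
        assert res.warnings  # the failure was recorded
        assert res.S[0, 0] == pytest.approx(1.0, rel=1e-2)

    def test_ranking_descends(self):
        B = np.diag([1.0, 5.0, 3.0])
        res = local_sensitivity(linear_residual(B, ("a", "b", "c")),
                                dict(a=1.0, b=1.0, c=1.0))
        assert res.ranking == ("b", "c", "a")


class TestMorrisScreening:
    def test_step_size_formula(self):
        # Delta = M/(2(M-1)); at M=60 this is about 0.508
        assert morris_step(60) == pytest.approx(60 / 118)
        assert morris_step(60) == pytest.approx(0.508, abs=5e-4)

    def test_linear_residual_has_zero_variance(self):
        names = ("a", "b")
        nominal = dict(a=2.0, b=4.0)
        cfg = SAConfig(K=20, M=8)

        def fn(theta):
            return np.array([3.0 * theta["a"] + 1.0 * theta["b"]])

        res = morris_screening(fn, nominal, cfg, seed=1)
        # elementary effects are constant: mu* = |coef| * range width
        assert np.allclose(res.sigma2, 0.0, atol=1e-18)
        width_a = 2.0 * cfg.stiffness_range * nominal["a"]
        width_b = 2.0 * cfg.stiffness_range * nominal["b"]
        assert res.mu_star[0] == pytest.approx(3.0 * width_a, rel=1e-9)
        assert res.mu_star[1] == pytest.approx(1.0 * width_b, rel=1e-9)

    def test_inert_parameter_ranked_last(self):
        def fn(theta):
            return np.array([theta["a"] ** 2])

        res = morris_screening(fn, dict(a=1.0, dead=1.0), SAConfig(K=10, M=8), seed=2)
        assert res.mu_star[1] == 0.0
        assert res.sigma2[1] == 0.0
        assert res.ranking[-1] == "dead"

    def test_deterministic_under_seed(self):
        def fn(theta):
            return np.array([theta["a"] * theta["b"], theta["a"] ** 2])

        nominal = dict(a=1.0, b=2.0)
        r1 = morris_screening(fn, nominal, SAConfig(K=15, M=8), seed=42)
        r2 = morris_screening(fn, nominal, SAConfig(K=15, M=8), seed=42)
        assert np.array_equal(r1.d_tilde, r2.d_tilde)

    def test_failed_trajectories_are_resampled(self):
        calls = {"n": 0}

        def fn(theta):
            calls["n"] += 1
            if calls["n"] % 7 == 3:
                raise RuntimeError("diverged")
            return np.array([theta["a"]])

        res = morris_screening(fn, dict(a=1.0), SAConfig(K=10, M=8), seed=3)
        assert res.d_tilde.shape == (10, 1)

    def test_top5_ranking_stable_across_seeds_and_matches_local(self):
        # a model with well separated parameter influences: the five most
        # influential labels agree between local and global rankings for
        # every seed
        names = tuple("p%d" % i for i in range(8))
        weights = {n: 10.0 ** (3 - 0.7 * i) for i, n in enumerate(names)}
        nominal = {n: 1.0 for n in names}

        def fn(theta):
            return np.array([sum(w * theta[n] for n, w in weights.items()),
                             weights["p0"] * theta["p0"] * theta["p1"]])

        loc = local_sensitivity(fn, nominal)
        top5_local = set(loc.ranking[:5])
        for seed in range(10):
            mor = morris_screening(fn, nominal, SAConfig(K=8, M=8), seed=seed)
            assert set(mor.ranking[:5]) == top5_local


class TestCorrelationAnalysis:
    def sens(self, S, names):
        from pulsetree.sensitivity import SensitivityResult

        S_bar = np.linalg.norm(S, axis=0)
        order = np.argsort(-S_bar)
        return SensitivityResult(names=names, S=S, S_bar=S_bar,
                                 ranking=tuple(names[i] for i in order))

    def test_orthogonal_columns_uncorrelated(self):
        S = np.eye(4)[:, :3] * 2.0
        res = correlation_analysis(self.sens(S, ("a", "b", "c")))
        assert np.allclose(res.corr, np.eye(3), atol=1e-12)
        assert res.flagged == ()

    def test_proportional_columns_flagged(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(8)
        S = np.column_stack([v, 2.0 * v + 1e-8 * rng.standard_normal(8),
                             rng.standard_normal(8)])
        res = correlation_analysis(self.sens(S, ("a", "b", "c")))
        flagged_pairs = {(a, b) for a, b, _ in res.flagged}
        assert ("a", "b") in flagged_pairs

    def test_three_parameter_hand_computed(self):
        # Gram matrix G = S^T S chosen by hand; correlation of the inverse
        S = np.array([[1.0, 1.0, 0.0],
                      [0.0, 1.0, 0.0],
                      [0.0, 0.0, 2.0]])
        res = correlation_analysis(self.sens(S, ("a", "b", "c")))
        G = S.T @ S
        V = np.linalg.inv(G)
        expect = V / np.sqrt(np.outer(np.diag(V), np.diag(V)))
        assert np.allclose(res.corr, expect, atol=1e-10)

    def test_invariant_to_observation_variance(self):
        rng = np.random.default_rng(2)
        S = rng.standard_normal((10, 4))
        sens = self.sens(S, ("a", "b", "c", "d"))
        c1 = correlation_analysis(sens, SAConfig(s2=1.0)).corr
        c2 = correlation_analysis(sens, SAConfig(s2=37.5)).corr
        assert np.allclose(c1, c2, atol=1e-12)

    def test_singular_information_matrix_flagged(self):
        v = np.arange(1.0, 6.0)
        S = np.column_stack([v, v])  # exactly collinear
        res = correlation_analysis(self.sens(S, ("a", "b")))
        assert res.rank_deficient


class TestSelectSubset:
    def make(self, S, names, morris_scores=None, seed=0):
        loc = TestCorrelationAnalysis().sens(S, names)
        if morris_scores is None:
            morris_scores = loc.S_bar
        from pulsetree.sensitivity import MorrisResult

        scores = np.asarray(morris_scores, dtype=float)
        order = np.argsort(-scores)
        mor = MorrisResult(names=names, d_tilde=np.zeros((1, len(names))),
                           mu_star=np.sqrt(scores), sigma2=np.zeros(len(names)),
                           score=scores, ranking=tuple(names[i] for i in order))
        corr = correlation_analysis(loc)
        return loc, mor, corr

    def test_all_influential_uncorrelated_keeps_all(self):
        S = np.eye(3) * 5.0
        sel = select_subset(*self.make(S, ("a", "b", "c")))
        assert set(sel.subset) == {"a", "b", "c"}

    def test_correlated_pair_drops_lower_ranked(self):
        v = np.arange(1.0, 7.0)
        S = np.column_stack([2.0 * v, v + 1e-9, np.ones(6)])
        sel = select_subset(*self.make(S, ("a", "b", "c")))
        assert "a" in sel.subset
        assert "b" not in sel.subset  # lower-ranked member of the pair
        assert any("b" in line for line in sel.log)

    def test_uninfluential_parameter_dropped(self):
        S = np.diag([10.0, 8.0, 1e-6])
        sel = select_subset(*self.make(S, ("a", "b", "weak")))
        assert "weak" not in sel.subset
        assert any("uninfluential" in line for line in sel.log)
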
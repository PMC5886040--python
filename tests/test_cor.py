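from fractions import Fraction

import numpy as np
import pytest

import heurbayes as hb
from heurbayes.comparisons import InputError
from conftest import exhaustive_inputs


@pytest.fixture(scope="module")
def toy_pairs():
    """Five integer comparisons on two correlated cues."""
    return hb.PairedComparisons(
        X=np.array([[1, 1], [1, 0], [-1, -1], [1, 1], [0, -1]]),
        y=np.array([1, -1, -1, 1, 1]),
        cue_names=["a", "b"],
    )


class TestCorWeights:
    def test_zero_penalty_reproduces_ols_in_every_column(self, env_pairs):
        w = hb.cor_weights(env_pairs, 0.0)
        ols = hb.ridge_weights(env_pairs, 0.0)
        for j in range(env_pairs.m):
            np.testing.assert_allclose(w.W[:, j], ols, atol=1e-8)

    def test_huge_penalty_suppresses_cross_weights(self, env_pairs):
        w = hb.cor_weights(env_pairs, 1e8)
        assert np.max(np.abs(w.cross)) < 1e-4 * np.max(np.abs(w.direct))

    def test_huge_penalty_diagonal_is_validity_transform(self, env_pairs):
        w = hb.cor_weights(env_pairs, 1e8)
        v = hb.cue_validity(env_pairs).validities
        np.testing.assert_allclose(np.diag(w.W), 2 * v - 1, atol=1e-4)

    def test_diagonal_identity_in_exact_arithmetic(self, toy_pairs):
        # The lambda->infinity diagonal is the simple-regression slope
        # sum(x y)/sum(x^2), which equals 2v-1 exactly in rationals.
        w = hb.cor_weights(toy_pairs, 1e10)
        for j in range(2):
            col = toy_pairs.X[:, j]
            slope = Fraction(int((col * toy_pairs.y).sum()), int((col**2).sum()))
            v = Fraction(int(((col * toy_pairs.y) == 1).sum()), int(np.abs(col).sum()))
            assert slope == 2 * v - 1
            assert w.W[j, j] == pytest.approx(float(slope), abs=1e-4)

    def test_orthogonal_design_diagonal_independent_of_penalty(self):
        # X'X diagonal: each direct weight is the simple-regression slope
        # at every lambda; cross-weights b_k/(G_kk + lambda) decay to 0.
        pc = hb.PairedComparisons(
            X=np.array([[1, 0], [-1, 0], [0, 1], [0, -1], [1, 0], [0, 1]]),
            y=np.array([1, -1, 1, -1, -1, 1]),
            cue_names=["a", "b"],
        )
        G = pc.X.T.astype(float) @ pc.X
        assert G[0, 1] == 0
        b = pc.X.T @ pc.y
        for lam in (1e-3, 1.0, 1e3):
            w = hb.cor_weights(pc, lam)
            np.testing.assert_allclose(w.direct, b / np.diag(G), atol=1e-12)
            for j in range(2):
                k = 1 - j
                assert w.W[k, j] == pytest.approx(b[k] / (G[k, k] + lam), abs=1e-12)

    def test_never_discriminating_cue_stays_zero(self):
        pc = hb.PairedComparisons(
            X=np.array([[1, 0], [-1, 0], [1, 0]]), y=np.array([1, -1, 1]),
            cue_names=["a", "dead"],
        )
        w = hb.cor_weights(pc, 1e8)
        assert abs(w.W[1, 1]) < 1e-8

    def test_cross_weight_norm_decays_monotonically(self, env_pairs):
        norms = [
            np.linalg.norm(hb.cor_weights(env_pairs, lam).cross)
            for lam in np.geomspace(1e-6, 1e8, 20)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-4 * max(norms[0], 1e-12)

    def test_singular_at_zero_penalty_advises_positive(self):
        pc = hb.PairedComparisons(
            X=np.array([[1, 1], [-1, -1]]), y=np.array([1, -1]), cue_names=["a", "b"]
        )
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            hb.cor_weights(pc, 0.0)

    def test_negative_penalty_rejected(self, env_pairs):
        with pytest.raises(InputError):
            hb.cor_weights(env_pairs, -1.0)


class TestOutputsAndRules:
    def test_identity_weights_pass_through(self):
        w = hb.CORWeights(W=np.eye(3), lmbda=1.0)
        np.testing.assert_array_equal(hb.cor_outputs(np.array([1, 0, -1]), w), [1, 0, -1])

    def test_zero_penalty_outputs_all_equal_ols_prediction(self, env_pairs):
        w = hb.cor_weights(env_pairs, 0.0)
        ols = hb.ridge_weights(env_pairs, 0.0)
        x = np.array([1, -1, 0, 1])
        out = hb.cor_outputs(x, w)
        np.testing.assert_allclose(out, np.full(4, x @ ols), atol=1e-8)

    def test_zero_input_gives_zero_outputs(self, env_pairs):
        w = hb.cor_weights(env_pairs, 1.0)
        assert np.allclose(hb.cor_outputs(np.zeros(4), w), 0)

    @pytest.mark.parametrize(
        "yhat,expected", [((0.2, -0.5, 0.1), -1), ((0.0, 0.0, 0.0), 0), ((0.5, -0.5), 1)]
    )
    def test_ttb_rule_examples(self, yhat, expected):
        assert hb.ttb_rule(np.array(yhat)) == expected

    @pytest.mark.parametrize(
        "yhat,expected", [((0.2, -0.5, 0.1), 1), ((0.2, -0.5), 0), ((-0.2, -0.5, -0.1), -1)]
    )
    def test_tally_rule_examples(self, yhat, expected):
        assert hb.tally_rule(np.array(yhat)) == expected

    def test_empty_output_rejected(self):
        with pytest.raises(InputError):
            hb.ttb_rule(np.array([]))
        with pytest.raises(InputError):
            hb.tally_rule(np.array([]))

    def test_rule_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            yhat = rng.normal(size=4)
            assert hb.ttb_rule(-yhat) == -hb.ttb_rule(yhat)
            assert hb.tally_rule(-yhat) == -hb.tally_rule(yhat)


@pytest.fixture(scope="module")
def trained():
    out = []
    for seed in range(5):
        spec = hb.EnvironmentSpec(
            m=4, n_objects=10, weight_scale=1.0, cue_correlation=0.3,
            noise_sd=1.0, directions=[1, -1, 1, -1], seed=200 + seed,
        )
        pc = hb.make_pairs(hb.generate_environment(spec))
        train, _ = hb.split_pairs(pc, 20, seed=seed)
        out.append((train, hb.cue_validity(train), hb.cor_weights(train, 1e8)))
    return out


class TestLimitEquivalences:
    def test_strong_prior_ttb_rule_is_take_the_best(self, trained):
        for _, prof, w in trained:
            for x in exhaustive_inputs(4):
                assert hb.cor_predict(x, w, "ttb_rule") == hb.take_the_best(x, prof)

    def test_strong_prior_tally_rule_is_undirected_tallying(self, trained):
        for _, prof, w in trained:
            for x in exhaustive_inputs(4):
                assert hb.cor_predict(x, w, "tally_rule") == hb.tally_undirected(x, prof)

    def test_zero_penalty_both_rules_follow_ols_sign(self, env_pairs):
        w = hb.cor_weights(env_pairs, 0.0)
        ols = hb.ridge_weights(env_pairs, 0.0)
        for x in exhaustive_inputs(4):
            z = x @ ols
            expected = 0 if abs(z) <= 1e-5 else int(np.sign(z))
            assert hb.cor_predict(x, w, "ttb_rule") == expected
            assert hb.cor_predict(x, w, "tally_rule") == expected

    def test_predict_antisymmetric_in_x(self, env_pairs):
        w = hb.cor_weights(env_pairs, 3.0)
        for rule in ("ttb_rule", "tally_rule"):
            for x in exhaustive_inputs(4)[::5]:
                assert hb.cor_predict(-x, w, rule) == -hb.cor_predict(x, w, rule)
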
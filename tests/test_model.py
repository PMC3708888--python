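import numpy as np
import pytest

from ccgibbs.dataset import ReactionVector, project_observations
from ccgibbs.model import (
    CCConfig,
    confidence_interval,
    estimate,
    fit_gc,
    fit_rc,
    load_model,
    prediction_interval,
    prediction_variance,
    save_model,
    train,
)
from conftest import incidence_from_matrix, training_data_from_matrices
from oracle_cc import oracle_estimate, oracle_train, random_instance


def _td(S, b):
    return training_data_from_matrices(np.asarray(S, float), np.asarray(b, float))


class TestFitRC:
    def test_disjoint_reactions_reproduce_values(self):
        # A->B at v1, C->D at v2; formation differences reproduce each exactly
        S = np.array([[-1, 0], [1, 0], [0, -1], [0, 1]], dtype=float)
        td = _td(S, [5.0, -3.0])
        dGf, fitted, res = fit_rc(td)
        np.testing.assert_allclose(fitted, [5.0, -3.0], atol=1e-10)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)
        assert dGf[1] - dGf[0] == pytest.approx(5.0)
        assert dGf[3] - dGf[2] == pytest.approx(-3.0)

    def test_consistent_system_zero_residual(self, rng):
        S = rng.integers(-2, 3, size=(5, 4)).astype(float)
        f_star = rng.normal(size=5)
        td = _td(S, S.T @ f_star)
        _, fitted, res = fit_rc(td)
        np.testing.assert_allclose(fitted, td.dG_obs, atol=1e-9)
        np.testing.assert_allclose(res, 0.0, atol=1e-9)

    def test_duplicated_reaction_fits_mean(self):
        S = np.array([[-1, -1], [1, 1]], dtype=float)
        td = _td(S, [2.0, 6.0])
        _, fitted, _ = fit_rc(td)
        np.testing.assert_allclose(fitted, [4.0, 4.0], atol=1e-10)


class TestFitGC:
    def test_identity_groups_reduce_to_rc(self, rng):
        S = rng.integers(-2, 3, size=(4, 5)).astype(float)
        b = rng.normal(size=5)
        td = _td(S, b)
        gi = incidence_from_matrix(np.eye(4), td.compound_index)
        dg, res_gc = fit_gc(td, gi)
        dGf, _, res_rc = fit_rc(td)
        np.testing.assert_allclose(dg, dGf, atol=1e-9)
        np.testing.assert_allclose(res_gc, res_rc, atol=1e-9)

    def test_single_group_scalar_least_squares(self):
        # reactions producing k net groups with value k*c fit dg = c exactly
        S = np.array([[-1, -2], [2, 3]], dtype=float)
        G = np.array([[1.0], [1.0]])  # net group change = column sums: 1, 1
        c = 4.0
        L = S.T @ G
        td = _td(S, (L * c).ravel())
        gi = incidence_from_matrix(G, td.compound_index)
        dg, res = fit_gc(td, gi)
        assert dg[0] == pytest.approx(c)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_untouched_group_gets_zero(self):
        # second group cancels in every reaction: minimal-norm solution is 0
        S = np.array([[-1, -1], [1, 1]], dtype=float)
        G = np.array([[2.0, 1.0], [3.0, 1.0]])
        td = _td(S, [1.0, 1.0])
        gi = incidence_from_matrix(G, td.compound_index)
        dg, _ = fit_gc(td, gi)
        assert dg[1] == pytest.approx(0.0, abs=1e-10)


class TestTrain:
    def test_identity_groups_reduce_to_rc_everywhere(self, rng):
        base = rng.integers(-2, 3, size=(5, 3)).astype(float)
        S = np.hstack([base, base @ rng.integers(-2, 3, size=(3, 2)).astype(float)])
        b = rng.normal(size=S.shape[1])
        td = _td(S, b)
        gi = incidence_from_matrix(np.eye(5), td.compound_index)
        model = train(td, gi)
        from ccgibbs.linalg import pseudoinverse

        St_pinv, _ = pseudoinverse(S.T)
        np.testing.assert_allclose(model.w, St_pinv @ b, atol=1e-9)
        # no GC variance contribution on range(S)
        x = S[:, 0]
        se2 = x @ model.V @ x
        sigma_rc_part = x @ (model.sigma2_rc * (St_pinv @ St_pinv.T)) @ x
        assert se2 == pytest.approx(sigma_rc_part, rel=1e-8)

    def test_matches_brute_force_oracle_small(self, rng):
        for _ in range(20):
            S, G, b = random_instance(rng)
            td = _td(S, b)
            gi = incidence_from_matrix(G, td.compound_index)
            model = train(td, gi)
            ora = oracle_train(S, G, b)
            np.testing.assert_allclose(model.w, ora["w"], atol=1e-8)
            np.testing.assert_allclose(model.V, ora["V"], atol=1e-8)
            assert model.rank_S == ora["rank_S"]
            assert model.rank_L == ora["rank_L"]

    def test_reaction_order_permutation_invariance(self, rng):
        S, G, b = random_instance(rng)
        td = _td(S, b)
        gi = incidence_from_matrix(G, td.compound_index)
        m1 = train(td, gi)
        perm = rng.permutation(S.shape[1])
        td2 = _td(S[:, perm], b[perm])
        m2 = train(td2, gi)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-9)
        np.testing.assert_allclose(m1.V, m2.V, atol=1e-9)

    def test_projected_observations_give_same_model(self, rng):
        """Projecting dG_obs first changes neither estimates nor variances."""
        S, G, b = random_instance(rng)
        td = _td(S, b)
        gi = incidence_from_matrix(G, td.compound_index)
        m_plain = train(td, gi)
        m_proj = train(project_observations(td), gi)
        np.testing.assert_allclose(m_plain.w, m_proj.w, atol=1e-9)
        assert m_plain.sigma2_rc == pytest.approx(m_proj.sigma2_rc, rel=1e-9)
        assert m_plain.sigma2_gc == pytest.approx(m_proj.sigma2_gc, rel=1e-9)
        np.testing.assert_allclose(m_plain.V, m_proj.V, atol=1e-9)

    def test_no_dof_raises(self):
        S = np.array([[-1.0], [1.0]])
        td = _td(S, [1.0])
        gi = incidence_from_matrix(np.eye(2), td.compound_index)
        with pytest.raises(ValueError, match="degrees of freedom"):
            train(td, gi)


@pytest.fixture
def trained(rng):
    S, G, b = random_instance(rng)
    td = _td(S, b)
    gi = incidence_from_matrix(G, td.compound_index)
    return train(td, gi), td, gi


class TestEstimate:
    def test_training_reaction_fixed_point(self, trained):
        model, td, _ = trained
        _, fitted, _ = fit_rc(td)
        for j in range(td.n_reactions):
            x = td.reaction_vector(j)
            if x.is_empty():
                continue
            est = estimate(model, x)
            assert est.dG0 == pytest.approx(fitted[j], abs=1e-8)
            assert est.rc_fraction == pytest.approx(1.0, abs=1e-8)

    def test_additivity_over_covered_reactions(self, trained):
        model, td, _ = trained
        x = td.reaction_vector(0)
        y = td.reaction_vector(1)
        combo = ReactionVector.from_dict(
            {
                c: x.as_dict().get(c, 0.0) + y.as_dict().get(c, 0.0)
                for c in set(x.compounds()) | set(y.compounds())
            }
        )
        lhs = estimate(model, combo).dG0
        rhs = estimate(model, x).dG0 + estimate(model, y).dG0
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_se_symmetric_under_reversal(self, trained):
        model, td, _ = trained
        x = td.reaction_vector(0)
        assert estimate(model, x).standard_error == pytest.approx(
            estimate(model, -x).standard_error, rel=1e-10
        )

    def test_unknown_compound_uncovered(self, trained):
        model, _, _ = trained
        est = estimate(model, ReactionVector.from_dict({"ZZZ": 1.0}))
        assert not est.covered
        assert est.standard_error >= 0.1 * model.config.alpha_inf

    def test_null_reaction_scores_zero(self, trained):
        model, _, _ = trained
        est = estimate(model, ReactionVector.from_dict({}))
        assert est.dG0 == 0.0
        assert est.standard_error == 0.0
        assert est.covered

    def test_matches_oracle_estimates(self, rng):
        S, G, b = random_instance(rng)
        td = _td(S, b)
        gi = incidence_from_matrix(G, td.compound_index)
        model = train(td, gi)
        ora = oracle_train(S, G, b)
        for _ in range(10):
            xd = rng.integers(-2, 3, size=S.shape[0]).astype(float)
            if not np.any(xd):
                continue
            x = ReactionVector.from_dict(
                {c: v for c, v in zip(td.compound_index, xd) if v != 0}
            )
            est = estimate(model, x)
            dg0_o, se_o, cov_o = oracle_estimate(ora, xd)
            assert est.dG0 == pytest.approx(dg0_o, abs=1e-6)
            assert est.standard_error == pytest.approx(se_o, rel=1e-6, abs=1e-6)
            assert est.covered == cov_o


class TestIntervals:
    def test_confidence_halfwidth_95(self, trained):
        model, td, _ = trained
        est = estimate(model, td.reaction_vector(0))
        lo, hi = confidence_interval(est, 0.95)
        half = (hi - lo) / 2
        assert half == pytest.approx(1.959963984540054 * est.standard_error, rel=1e-9)

    def test_interval_collapses_and_nests(self, trained):
        model, td, _ = trained
        est = estimate(model, td.reaction_vector(0))
        lo_s, hi_s = confidence_interval(est, 1e-9)
        assert hi_s - lo_s == pytest.approx(0.0, abs=1e-6 * max(est.standard_error, 1))
        lo1, hi1 = confidence_interval(est, 0.68)
        lo2, hi2 = confidence_interval(est, 0.95)
        assert lo2 < lo1 < hi1 < hi2

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_level_rejected(self, trained, bad):
        model, td, _ = trained
        est = estimate(model, td.reaction_vector(0))
        with pytest.raises(ValueError):
            confidence_interval(est, bad)

    def test_prediction_variance_weights(self, trained):
        model, td, _ = trained
        # fully in range(S): weight 1 on the RC variance
        x = td.reaction_vector(0)
        assert prediction_variance(model, x) == pytest.approx(
            model.sigma2_rc, rel=1e-8
        )
        # manual check of the squared-norm mixing for an arbitrary query
        xd = np.zeros(model.n_compounds)
        xd[0], xd[-1] = 1.0, -1.0
        q = ReactionVector.from_dict(
            {model.compound_index[0]: 1.0, model.compound_index[-1]: -1.0}
        )
        fr = np.linalg.norm(model.P_R @ xd) ** 2 / (xd @ xd)
        expected = fr * model.sigma2_rc + (1 - fr) * model.sigma2_gc
        assert prediction_variance(model, q) == pytest.approx(expected, rel=1e-8)

    def test_prediction_interval_widens_confidence(self, trained):
        model, td, _ = trained
        x = td.reaction_vector(0)
        est = estimate(model, x)
        lo_c, hi_c = confidence_interval(est, 0.95)
        lo_p, hi_p = prediction_interval(model, x, 0.95)
        assert lo_p <= lo_c and hi_p >= hi_c

    def test_uncovered_prediction_interval_infinite(self, trained):
        model, _, _ = trained
        lo, hi = prediction_interval(
            model, ReactionVector.from_dict({"ZZZ": 1.0}), 0.95
        )
        assert lo == float("-inf") and hi == float("inf")


def test_model_serialization_round_trip(tmp_path, trained):
    model, td, _ = trained
    p = tmp_path / "model.json"
    save_model(p, model, header={"note": "test"})
    back = load_model(p)
    x = td.reaction_vector(0)
    e1, e2 = estimate(model, x), estimate(back, x)
    assert e1.dG0 == pytest.approx(e2.dG0, rel=1e-12)
    assert e1.standard_error == pytest.approx(e2.standard_error, rel=1e-12)
    assert e1.covered == e2.covered
    np.testing.assert_allclose(model.w, back.w)
    assert back.config == model.config
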
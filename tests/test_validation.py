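import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import expit, logit
from scipy.stats import binom

import geomort as gm
from geomort.model import ClusterData
from geomort.validation import data_checksum

from conftest import make_samples


def brute_waic(L):
    """Straight-line reimplementation from the defining formulas."""
    S, n = L.shape
    lppd = 0.0
    p_waic = 0.0
    for i in range(n):
        col = L[:, i]
        lppd += np.log(np.mean(np.exp(col)))
        p_waic += np.var(col, ddof=1)
    return -2 * (lppd - p_waic), p_waic, lppd


@pytest.fixture
def toy():
    y = np.array([2.0, 0.0, 7.0])
    n = np.array([9.0, 5.0, 12.0])
    data = ClusterData(y=y, n=n, cell=np.zeros(3), survey=np.zeros(3))
    return data, np.zeros((3, 0))


class TestPointwiseLoglik:
    def test_plugin_draw_reproduces_maximized_pmf(self):
        y = np.array([3.0])
        n = np.array([10.0])
        data = ClusterData(y=y, n=n, cell=[0], survey=[0])
        samples = make_samples(alpha=np.array([[logit(0.3)]]))
        L = gm.pointwise_loglik(samples, data, np.zeros((1, 0)))
        assert L.shape == (1, 1)
        assert L[0, 0] == pytest.approx(float(binom.logpmf(3, 10, 0.3)),
                                        abs=1e-12)

    def test_rows_sum_to_total_log_likelihood(self, small_fit):
        samples, spec, design, data = small_fit
        L = samples.loglik
        from geomort.model import LatentState, log_likelihood

        for s in (0, L.shape[0] // 2, L.shape[0] - 1):
            state = LatentState(
                alpha=samples.alpha_flat[s], beta=samples.beta_flat[s],
                zeta=np.zeros(0), sigma=1.0)
            assert L[s].sum() == pytest.approx(
                log_likelihood(state, data, design.X), abs=1e-9)

    def test_matches_direct_pmf(self, toy):
        data, X = toy
        rng = np.random.default_rng(4)
        etas = rng.normal(size=(2, 1))
        samples = make_samples(alpha=etas)
        L = gm.pointwise_loglik(samples, data, X)
        oracle = binom.logpmf(data.y, data.n, expit(etas))
        np.testing.assert_allclose(L, oracle, atol=1e-12)


class TestCPO:
    def test_single_draw_is_the_likelihood(self, toy):
        data, X = toy
        samples = make_samples(alpha=np.array([[0.3]]))
        L = gm.pointwise_loglik(samples, data, X)
        cpo, reliable = gm.compute_cpo(L)
        np.testing.assert_allclose(cpo, np.exp(L[0]), atol=1e-14)
        assert reliable.all()

    def test_degenerate_posterior_is_the_likelihood(self, toy):
        data, X = toy
        samples = make_samples(alpha=np.full((50, 1), -0.4))
        L = gm.pointwise_loglik(samples, data, X)
        cpo, reliable = gm.compute_cpo(L)
        np.testing.assert_allclose(cpo, np.exp(L[0]), rtol=1e-12)
        assert reliable.all()

    def test_cpo_bounded_for_discrete_data(self, small_fit):
        samples, spec, design, data = small_fit
        cpo, _ = gm.compute_cpo(samples.loglik)
        assert np.all(cpo > 0) and np.all(cpo <= 1)

    def test_unstable_weights_flagged(self):
        # one extreme outlying draw dominates the harmonic mean
        L = np.full((100, 1), -1.0)
        L[0, 0] = -60.0
        _, reliable = gm.compute_cpo(L)
        assert not reliable[0]


class TestPIT:
    def test_zero_count_boundary(self, toy):
        data, X = toy
        samples = make_samples(alpha=np.array([[-0.2], [0.4]]))
        pit = gm.compute_pit(samples, data, X)
        # observation 1 has y = 0: PIT = 0.5 * P(Y=0) <= 0.5
        assert pit[1] <= 0.5
        assert np.all((pit >= 0) & (pit <= 1))

    def test_saturated_count_boundary(self):
        data = ClusterData(y=[6.0], n=[6.0], cell=[0], survey=[0])
        samples = make_samples(alpha=np.array([[0.1], [-0.3]]))
        pit = gm.compute_pit(samples, data, np.zeros((1, 0)))
        assert pit[0] >= 0.5

    def test_mid_pit_identity_single_draw(self):
        data = ClusterData(y=[2.0], n=[8.0], cell=[0], survey=[0])
        eta = 0.3
        samples = make_samples(alpha=np.array([[eta]]))
        pit = gm.compute_pit(samples, data, np.zeros((1, 0)))
        p = expit(eta)
        expected = binom.cdf(1, 8, p) + 0.5 * binom.pmf(2, 8, p)
        assert pit[0] == pytest.approx(float(expected), abs=1e-12)


class TestWAIC:
    def test_constant_draws_have_zero_penalty(self):
        L = np.tile(np.array([-1.2, -0.7, -2.0]), (5, 1))
        waic, p_waic, lppd = gm.compute_waic(L)
        assert p_waic == pytest.approx(0.0, abs=1e-12)
        assert waic == pytest.approx(-2 * L[0].sum(), abs=1e-10)

    def test_duplicating_observations_doubles_everything(self):
        rng = np.random.default_rng(6)
        L = -rng.exponential(size=(7, 5))
        w1, p1, l1 = gm.compute_waic(L)
        w2, p2, l2 = gm.compute_waic(np.hstack([L, L]))
        assert w2 == pytest.approx(2 * w1, rel=1e-12)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        L = -rng.exponential(size=(5, 4))
        waic, p_waic, lppd = gm.compute_waic(L)
        bw, bp, bl = brute_waic(L)
        assert waic == pytest.approx(bw, abs=1e-10)
        assert p_waic == pytest.approx(bp, abs=1e-10)
        assert lppd == pytest.approx(bl, abs=1e-10)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            gm.compute_waic(np.zeros((1, 3)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.float64, (6, 5),
                  elements=st.floats(-30, -0.01, allow_nan=False)),
           st.integers(0, 10_000))
    def test_invariant_to_permutations_and_jensen(self, L, perm_seed):
        rng = np.random.default_rng(perm_seed)
        w1 = gm.compute_waic(L)
        w2 = gm.compute_waic(L[rng.permutation(6)][:, rng.permutation(5)])
        assert w1[0] == pytest.approx(w2[0], rel=1e-9, abs=1e-9)
        # Jensen: lppd >= mean of pointwise log-likelihoods
        assert w1[2] >= L.mean(axis=0).sum() - 1e-9
        # importance-weighting penalty: sum log CPO <= lppd
        cpo, _ = gm.compute_cpo(L)
        assert np.log(cpo).sum() <= w1[2] + 1e-9


class TestCompareModels:
    def report(self, L, name, n_par, checksum="abc"):
        waic, p_waic, lppd = gm.compute_waic(L)
        return gm.ValidationReport(
            model_name=name, cpo=np.ones(L.shape[1]),
            cpo_reliable=np.ones(L.shape[1], bool), pit=np.full(L.shape[1], 0.5),
            waic=waic, p_waic=p_waic, lppd=lppd, n_parameters=n_par,
            data_checksum=checksum)

    def test_sorted_ascending_by_waic(self):
        rng = np.random.default_rng(8)
        L = -rng.exponential(size=(10, 6))
        better = self.report(L, "good", 3)
        worse = self.report(L - 0.5, "bad", 3)
        ranking = gm.compare_models([worse, better])
        assert list(ranking["model"]) == ["good", "bad"]
        assert ranking["delta_waic"].iloc[0] == 0.0
        assert (ranking["delta_waic"] >= 0).all()

    def test_exact_tie_prefers_fewer_parameters(self):
        rng = np.random.default_rng(9)
        L = -rng.exponential(size=(10, 6))
        a = self.report(L, "small", 2)
        b = self.report(L, "large", 5)
        assert gm.compare_models([b, a])["model"].iloc[0] == "small"

    def test_single_report_is_best(self):
        r = self.report(-np.random.default_rng(10).exponential(size=(5, 3)),
                        "only", 1)
        assert gm.compare_models([r])["model"].tolist() == ["only"]

    def test_mixed_datasets_rejected(self):
        rng = np.random.default_rng(11)
        a = self.report(-rng.exponential(size=(5, 3)), "a", 1, checksum="x")
        b = self.report(-rng.exponential(size=(5, 3)), "b", 1, checksum="y")
        with pytest.raises(ValueError, match="different datasets"):
            gm.compare_models([a, b])

    def test_checksum_tracks_data(self, toy):
        data, _ = toy
        same = ClusterData(y=data.y.copy(), n=data.n.copy(),
                           cell=data.cell.copy(), survey=data.survey.copy())
        other = ClusterData(y=data.y + 1, n=data.n + 2, cell=data.cell,
                            survey=data.survey)
        assert data_checksum(data) == data_checksum(same)
        assert data_checksum(data) != data_checksum(other)
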
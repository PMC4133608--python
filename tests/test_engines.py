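"""CE and QM engine tests: dense-oracle agreement, the cross-engine
identity, projection-matrix invariants, GBLUP and per-SNP partitions."""

import time

import numpy as np
import pytest

from adgreml.engine_ce import CeEngine
from adgreml.engine_qm import QmEngine
from adgreml.model_matrices import GrmPair
from adgreml.reml_core import hybrid_driver

from _oracle import (
    naive_P,
    naive_V,
    naive_gblup,
    naive_quadratics,
    naive_snp_effects,
    naive_snp_variances,
)
from conftest import make_dataset

THETA = np.array([0.35, 0.25, 0.40])


@pytest.fixture(scope="module", params=["ce", "qm"])
def engine_cls(request):
    return {"ce": CeEngine, "qm": QmEngine}[request.param]


class TestQuadraticsAgainstOracle:
    def test_f1_quadratics_match_dense_reference(self, f1_model, engine_cls):
        mm, grm = f1_model
        eng = engine_cls(mm, grm, mm.y)
        q = eng.quadratics(THETA)
        yPHPy, trPH, AI, logL = naive_quadratics(THETA, mm.Z, grm.A_g, grm.D_g, mm.X, mm.y)
        np.testing.assert_allclose(q.yPHPy, yPHPy, rtol=1e-8)
        np.testing.assert_allclose(q.trPH, trPH, rtol=1e-8)
        np.testing.assert_allclose(q.AI, AI, rtol=1e-8, atol=1e-10)
        assert q.logL == pytest.approx(logL, rel=1e-10)

    def test_quadratics_match_oracle_with_validation_and_factor(self, small_dataset, engine_cls):
        _, _, _, mm, grm = small_dataset
        eng = engine_cls(mm, grm, mm.y)
        q = eng.quadratics(THETA)
        yPHPy, trPH, AI, logL = naive_quadratics(THETA, mm.Z, grm.A_g, grm.D_g, mm.X, mm.y)
        np.testing.assert_allclose(q.yPHPy, yPHPy, rtol=1e-8)
        np.testing.assert_allclose(q.trPH, trPH, rtol=1e-8)
        np.testing.assert_allclose(q.AI, AI, rtol=1e-8, atol=1e-10)
        assert q.logL == pytest.approx(logL, rel=1e-8)

    def test_trace_identity_and_ai_psd_on_random_fixtures(self, engine_cls):
        """sigma2 . trPH = N - rank(X) (since tr(PV) = N - rank X) and the
        AI matrix is symmetric PSD, across random datasets."""
        for seed in range(10):
            _, _, _, mm, grm = make_dataset(20, 8, seed=seed, fixed=seed % 2 == 0)
            eng = engine_cls(mm, grm, mm.y)
            theta = np.random.default_rng(seed).uniform(0.1, 1.0, 3)
            q = eng.quadratics(theta)
            lhs = float(theta @ q.trPH)
            assert lhs == pytest.approx(mm.n_records - mm.rank_X, rel=1e-8)
            np.testing.assert_allclose(q.AI, q.AI.T, atol=1e-12)
            assert np.linalg.eigvalsh(q.AI).min() > -1e-10


class TestProjectionInvariants:
    def test_PX_zero_PVP_P(self, small_dataset):
        _, _, _, mm, grm = small_dataset
        eng = CeEngine(mm, grm, mm.y)
        eng.quadratics(THETA)
        P = eng._state["P"]
        V = eng._state["V"]
        assert np.abs(P @ mm.X).max() <= 1e-8 * np.abs(P).max()
        np.testing.assert_allclose(P @ V @ P, P, rtol=1e-8, atol=1e-12)
        assert np.trace(P @ V) == pytest.approx(mm.n_records - mm.rank_X, rel=1e-8)

    def test_apply_P_qm_equals_dense_P(self, small_dataset):
        _, _, _, mm, grm = small_dataset
        eng = QmEngine(mm, grm, mm.y)
        eng.quadratics(THETA)
        P = naive_P(naive_V(THETA, mm.Z, grm.A_g, grm.D_g), mm.X)
        rng = np.random.default_rng(2)
        v = rng.standard_normal(mm.n_records)
        np.testing.assert_allclose(eng.apply_P(v), P @ v, rtol=1e-8, atol=1e-12)
        # PX = 0 and PVP = P through the operator
        b = rng.standard_normal(mm.X.shape[1])
        assert np.abs(eng.apply_P(mm.X @ b)).max() < 1e-8
        V = naive_V(THETA, mm.Z, grm.A_g, grm.D_g)
        Py = eng.apply_P(mm.y)
        np.testing.assert_allclose(eng.apply_P(V @ Py), Py, rtol=1e-8)

    def test_ce_limit_is_centering_projection(self):
        """With genetic variances at the floor and no covariates,
        P -> (I - 11'/N) / sigma2_e."""
        _, _, _, mm, grm = make_dataset(10, 5, seed=3)
        eng = CeEngine(mm, grm, mm.y)
        se = 0.7
        eng.quadratics(np.array([1e-12, 1e-12, se]))
        P = eng._state["P"]
        N = mm.n_records
        expected = (np.eye(N) - np.ones((N, N)) / N) / se
        np.testing.assert_allclose(P, expected, atol=1e-9)


class TestEngineEquivalence:
    def test_full_driver_trajectory_identical(self, small_dataset):
        """The headline equivalence: both formulations yield the same GREML
        trajectory, estimates, GBLUPs and per-SNP quantities."""
        _, phen, _, mm, grm = small_dataset
        res_ce = hybrid_driver(CeEngine(mm, grm, mm.y), mm.y, max_iterations=50)
        res_qm = hybrid_driver(QmEngine(mm, grm, mm.y), mm.y, max_iterations=50)
        assert len(res_ce.records) == len(res_qm.records)
        for rc, rq in zip(res_ce.records, res_qm.records):
            assert rc.algorithm == rq.algorithm
            np.testing.assert_allclose(
                rc.theta.as_array(), rq.theta.as_array(), rtol=1e-6
            )
            assert rc.logL == pytest.approx(rq.logL, rel=1e-6)

    def test_gblup_and_snp_outputs_identical(self, small_dataset):
        _, _, _, mm, grm = small_dataset
        ce = CeEngine(mm, grm, mm.y)
        qm = QmEngine(mm, grm, mm.y)
        for eng in (ce, qm):
            eng.quadratics(THETA)
        g_ce = ce.gblup(THETA)
        g_qm = qm.gblup(THETA)
        np.testing.assert_allclose(g_ce.a_hat, g_qm.a_hat, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(g_ce.d_hat, g_qm.d_hat, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(g_ce.rel_a, g_qm.rel_a, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(g_ce.rel_g, g_qm.rel_g, rtol=1e-6, atol=1e-10)
        a_ce, d_ce = ce.snp_effects(THETA)
        a_qm, d_qm = qm.snp_effects(THETA)
        np.testing.assert_allclose(a_ce, a_qm, rtol=1e-6, atol=1e-12)
        t_ce = ce.snp_variances(THETA, a_ce, d_ce, 1.0)
        t_qm = qm.snp_variances(THETA, a_qm, d_qm, 1.0)
        np.testing.assert_allclose(
            t_ce.sigma2_alpha_i, t_qm.sigma2_alpha_i, rtol=1e-6, atol=1e-12
        )
        np.testing.assert_allclose(
            t_ce.sigma2_delta_i, t_qm.sigma2_delta_i, rtol=1e-6, atol=1e-12
        )


class TestGblup:
    def test_matches_dense_oracle(self, small_dataset, engine_cls):
        _, _, _, mm, grm = small_dataset
        eng = engine_cls(mm, grm, mm.y)
        res = eng.gblup(THETA)
        a, d = naive_gblup(THETA, mm.Z, grm.A_g, grm.D_g, mm.X, mm.y)
        np.testing.assert_allclose(res.a_hat, a, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(res.d_hat, d, rtol=1e-8, atol=1e-12)

    def test_g_hat_is_sum_and_reliabilities_bounded(self, small_dataset, engine_cls):
        _, _, _, mm, grm = small_dataset
        eng = engine_cls(mm, grm, mm.y)
        res = eng.gblup(THETA)
        np.testing.assert_array_equal(res.g_hat, res.a_hat + res.d_hat)
        for rel in (res.rel_a, res.rel_d, res.rel_g):
            assert np.all(rel >= -1e-10) and np.all(rel <= 1 + 1e-10)

    def test_validation_individuals_get_predictions(self, small_dataset, engine_cls):
        _, phen, _, mm, grm = small_dataset
        eng = engine_cls(mm, grm, mm.y)
        res = eng.gblup(THETA, training_ids=set(phen.training_ids))
        val = [i for i, s in enumerate(res.sets) if s == "validation"]
        assert len(val) == 2
        assert np.all(np.isfinite(np.asarray(res.a_hat)[val]))

    def test_unrelated_validation_individual_predicts_zero(self):
        """An individual with a zero relationship row to the training set
        gets a_hat = 0 and rel_a = 0."""
        _, _, _, mm, grm = make_dataset(8, 5, seed=13, n_validation=1)
        A = grm.A_g.copy()
        D = grm.D_g.copy()
        A[-1, :] = A[:, -1] = 0.0
        D[-1, :] = D[:, -1] = 0.0
        res = CeEngine(mm, GrmPair(A, D, 1), mm.y).gblup(THETA)
        assert res.a_hat[-1] == 0.0 and res.rel_a[-1] == 0.0


class TestSnpPartition:
    def test_effects_match_oracle_and_rebuild_gblup(self, small_dataset, engine_cls):
        _, _, _, mm, grm = small_dataset
        eng = engine_cls(mm, grm, mm.y)
        alpha, delta = eng.snp_effects(THETA)
        a_o, d_o = naive_snp_effects(THETA, mm.Z, mm.T_alpha, mm.T_delta,
                                     grm.A_g, grm.D_g, mm.X, mm.y)
        np.testing.assert_allclose(alpha, a_o, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(delta, d_o, rtol=1e-8, atol=1e-12)
        # a = T_alpha alpha: back-solved marker effects reproduce the GBLUP
        res = eng.gblup(THETA)
        np.testing.assert_allclose(mm.T_alpha @ alpha, res.a_hat, rtol=1e-8, atol=1e-12)

    def test_per_snp_variances_match_oracle(self, small_dataset, engine_cls):
        _, _, _, mm, grm = small_dataset
        eng = engine_cls(mm, grm, mm.y)
        alpha, delta = eng.snp_effects(THETA)
        table = eng.snp_variances(THETA, alpha, delta, 1.0)
        s2a, s2d = naive_snp_variances(THETA, mm.Z, mm.T_alpha, mm.T_delta,
                                       grm.A_g, grm.D_g, mm.X, mm.y)
        np.testing.assert_allclose(table.sigma2_alpha_i, s2a, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(table.sigma2_delta_i, s2d, rtol=1e-8, atol=1e-12)

    def test_partition_sums_to_total_heritability_at_convergence(self, engine_cls):
        _, _, _, mm, grm = make_dataset(120, 60, h2a=0.35, h2d=0.25, seed=17)
        eng = engine_cls(mm, grm, mm.y)
        res = hybrid_driver(eng, mm.y)
        assert res.converged
        theta = res.components.as_array()
        alpha, delta = eng.snp_effects(theta)
        table = eng.snp_variances(theta, alpha, delta, res.heritabilities.sigma2_p)
        assert table.h2_alpha_i.sum() == pytest.approx(res.heritabilities.h2_alpha, abs=1e-6)
        assert table.h2_delta_i.sum() == pytest.approx(res.heritabilities.h2_delta, abs=1e-6)


class TestComplementaryScaling:
    def test_ce_iteration_cost_independent_of_marker_count(self):
        """CE quadratics work in the record dimension: once the GRMs are
        built, iteration time does not grow with m."""
        times = {}
        for m in (200, 2000):
            _, _, _, mm, grm = make_dataset(300, m, seed=23)
            eng = CeEngine(mm, grm, mm.y)
            eng.quadratics(THETA)  # warm
            reps = []
            for k in range(5):
                eng._cache_theta = None
                t0 = time.perf_counter()
                eng.quadratics(THETA + 1e-6 * k)
                reps.append(time.perf_counter() - t0)
            times[m] = min(reps)
        assert times[2000] < 2.0 * times[200] + 0.05

    def test_qm_iteration_cost_independent_of_individual_count(self):
        """QM quadratics work in the marker dimension after the
        cross-products are absorbed."""
        times = {}
        for q in (500, 5000):
            _, _, _, mm, grm = make_dataset(q, 100, seed=29)
            eng = QmEngine(mm, grm, mm.y)
            eng.quadratics(THETA)
            reps = []
            for k in range(5):
                eng._cache_theta = None
                t0 = time.perf_counter()
                eng.quadratics(THETA + 1e-6 * k)
                reps.append(time.perf_counter() - t0)
            times[q] = min(reps)
        assert times[5000] < 2.0 * times[500] + 0.05
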
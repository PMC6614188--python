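import math

import numpy as np
import pytest
from scipy import stats

import txanomaly as tx
from txanomaly.detector import _spectrum_moments


def orthonormal(p, k, rng):
    q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    return q


def centered(z):
    return z - z.mean(axis=1, keepdims=True)


class TestFitSubspace:
    def test_exact_low_rank_data(self):
        rng = np.random.default_rng(0)
        basis = orthonormal(20, 2, rng)
        z = centered(basis @ rng.standard_normal((2, 15)))
        loadings, ev, k = tx.fit_subspace(z, k=2)
        assert k == 2
        scores = tx.residue_score(loadings, z)
        assert scores.max() < 1e-16
        assert (ev > 1e-10 * ev[0]).sum() == 2

    def test_matches_dense_covariance_eigendecomposition(self):
        # 30 genes x 20 samples against an explicit p x p covariance oracle
        rng = np.random.default_rng(1)
        z = centered(rng.standard_normal((30, 20)))
        _, ev, _ = tx.fit_subspace(z, k=3)
        cov = z @ z.T / 19
        dense = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(ev, dense[: ev.size], rtol=1e-8, atol=1e-10)

    @staticmethod
    def data_with_eigenvalue_shares(shares, n=40, seed=3):
        rng = np.random.default_rng(seed)
        p = len(shares)
        u = orthonormal(p, p, rng)
        v = orthonormal(n, p, rng)
        s = np.sqrt(np.asarray(shares) * (n - 1))
        return u @ np.diag(s) @ v.T

    def test_variance_fraction_rule(self):
        z = self.data_with_eigenvalue_shares([0.6, 0.3, 0.08, 0.02])
        _, _, k = tx.fit_subspace(z, variance_fraction=0.9)
        assert k == 2

    def test_variance_fraction_hitting_rank_is_degenerate(self):
        z = self.data_with_eigenvalue_shares([0.6, 0.3, 0.08, 0.02])
        with pytest.raises(tx.DetectorError, match="residue degenerate"):
            tx.fit_subspace(z, variance_fraction=0.99)

    def test_fixed_k_at_rank_rejected(self):
        rng = np.random.default_rng(4)
        z = centered(rng.standard_normal((5, 30)))
        with pytest.raises(tx.DetectorError, match="residue degenerate"):
            tx.fit_subspace(z, k=5)

    def test_too_few_samples(self):
        with pytest.raises(tx.DetectorError, match="3 samples"):
            tx.fit_subspace(np.ones((4, 2)))


class TestResidueScore:
    def test_zero_vector_scores_zero(self):
        rng = np.random.default_rng(5)
        loadings = orthonormal(10, 3, rng)
        assert tx.residue_score(loadings, np.zeros(10)) == 0.0

    def test_basis_vectors_score_zero(self):
        rng = np.random.default_rng(6)
        loadings = orthonormal(30, 4, rng)
        for j in range(4):
            assert tx.residue_score(loadings, loadings[:, j]) < 1e-16

    def test_matches_explicit_projection_oracle(self):
        # brute force: form P P^T, subtract the reconstruction, square-sum
        rng = np.random.default_rng(7)
        loadings = orthonormal(50, 5, rng)
        z = rng.standard_normal((50, 100))
        projector = loadings @ loadings.T
        expected = ((z - projector @ z) ** 2).sum(axis=0)
        np.testing.assert_allclose(
            tx.residue_score(loadings, z), expected, rtol=1e-8
        )

    def test_invariant_to_rotation_of_the_retained_basis(self):
        rng = np.random.default_rng(8)
        loadings = orthonormal(40, 6, rng)
        rotation = orthonormal(6, 6, rng)
        z = rng.standard_normal((40, 50))
        np.testing.assert_allclose(
            tx.residue_score(loadings, z),
            tx.residue_score(loadings @ rotation, z),
            rtol=1e-8,
        )

    def test_pythagorean_decomposition(self):
        rng = np.random.default_rng(9)
        loadings = orthonormal(25, 5, rng)
        z = rng.standard_normal((25, 40))
        within = (loadings.T @ z) ** 2
        total = (z**2).sum(axis=0)
        np.testing.assert_allclose(
            tx.residue_score(loadings, z) + within.sum(axis=0), total, rtol=1e-8
        )

    def test_orthogonal_component_never_decreases_score(self):
        rng = np.random.default_rng(10)
        loadings = orthonormal(25, 5, rng)
        z = rng.standard_normal(25)
        extra = rng.standard_normal(25)
        extra -= loadings @ (loadings.T @ extra)
        for scale in (0.0, 0.5, 1.0, 2.0):
            lesser = tx.residue_score(loadings, z)
            greater = tx.residue_score(loadings, z + scale * extra)
            assert greater >= lesser - 1e-12

    def test_length_mismatch(self):
        rng = np.random.default_rng(11)
        with pytest.raises(tx.DetectorError, match="length"):
            tx.residue_score(orthonormal(10, 2, rng), np.zeros(9))


class TestJMThreshold:
    def test_single_discarded_eigenvalue_gives_h0_one_third(self):
        jm = tx.jm_threshold(np.array([5.0, 2.0]), k=1, alpha=0.05)
        assert jm.h0 == pytest.approx(1.0 / 3.0)
        assert jm.theta1 == 2.0 and jm.theta2 == 4.0 and jm.theta3 == 8.0

    def test_median_alpha_simplification(self):
        # alpha = 0.5 makes c_alpha = 0 and the bracket loses its first term
        ev = np.array([4.0, 2.0, 1.0, 0.5])
        jm = tx.jm_threshold(ev, k=2, alpha=0.5)
        t1, t2, t3, h0 = _spectrum_moments(ev, 2)
        expected = t1 * (1 + t2 * h0 * (h0 - 1) / t1**2) ** (1 / h0)
        assert jm.c_alpha == 0.0
        assert jm.q_threshold == pytest.approx(expected, rel=1e-12)

    def test_all_discarded_zero_is_an_error(self):
        with pytest.raises(tx.DetectorError, match="discarded"):
            tx.jm_threshold(np.array([3.0, 0.0, 0.0]), k=1, alpha=0.05)

    def test_nonpositive_bracket_advises_empirical(self):
        with pytest.raises(tx.DetectorError, match="empirical"):
            tx.jm_threshold(np.array([5.0, 2.0]), k=1, alpha=0.9999)

    def test_calibrated_on_gaussian_residuals(self):
        # threshold from the true spectrum of iid normals: tail prob close to alpha
        rng = np.random.default_rng(12)
        ev = np.ones(40)
        jm = tx.jm_threshold(ev, k=5, alpha=0.05)
        q = rng.chisquare(35, size=20000)
        assert 0.03 < (q > jm.q_threshold).mean() < 0.08


class TestEmpiricalThreshold:
    def test_brackets_order_statistics(self):
        scores = np.arange(1.0, 101.0)
        t = tx.empirical_threshold(scores, alpha=0.05)
        assert 95.0 <= t <= 96.0

    def test_constant_scores(self):
        assert tx.empirical_threshold(np.full(50, 3.25), alpha=0.1) == 3.25

    def test_too_few_scores(self):
        with pytest.raises(tx.DetectorError, match="20"):
            tx.empirical_threshold(np.arange(10.0), alpha=0.05)

    def test_uniform_quantile_oracle(self):
        rng = np.random.default_rng(13)
        t = tx.empirical_threshold(rng.uniform(0, 1, 10000), alpha=0.1)
        assert 0.88 < t < 0.92

    def test_agrees_with_jm_on_well_behaved_spectra(self):
        # iid gaussian training data, n >> p: the two thresholds nearly coincide
        rng = np.random.default_rng(14)
        z = centered(rng.standard_normal((20, 2000)))
        z /= z.std(axis=1, ddof=1, keepdims=True)
        loadings, ev, k = tx.fit_subspace(z, k=4)
        q_jm = tx.jm_threshold(ev, k, alpha=0.05).q_threshold
        q_emp = tx.empirical_threshold(tx.residue_score(loadings, z), alpha=0.05)
        assert abs(q_jm - q_emp) / q_emp < 0.15


class TestClassify:
    def make_model(self):
        rng = np.random.default_rng(15)
        loadings = orthonormal(8, 2, rng)
        ev = np.array([5.0, 3.0, 1.0, 0.5, 0.2, 0.1])
        s = tx.Standardizer(
            gene_ids=[f"G{i}" for i in range(8)],
            means=np.zeros(8), sds=np.ones(8), min_sd=0.0,
        )
        jm = tx.jm_threshold(ev, 2, 0.05)
        return tx.DetectorModel(
            standardizer=s, loadings=loadings, eigenvalues=ev, k=2, alpha=0.05,
            theta1=jm.theta1, theta2=jm.theta2, theta3=jm.theta3, h0=jm.h0,
            c_alpha=jm.c_alpha, q_threshold=jm.q_threshold,
        )

    def test_tie_with_threshold_is_called_normal(self):
        model = self.make_model()
        # build a vector orthogonal to the subspace with squared norm == q
        rng = np.random.default_rng(16)
        v = rng.standard_normal(8)
        v -= model.loadings @ (model.loadings.T @ v)
        model.q_threshold = float(tx.residue_score(model.loadings, v))
        table = tx.classify(model, v)
        assert table["call"].iloc[0] == "normal"
        assert table["log_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_vector_is_normal_with_minus_inf_log_ratio(self):
        model = self.make_model()
        table = tx.classify(model, np.zeros(8))
        assert table["score"].iloc[0] == 0.0
        assert table["call"].iloc[0] == "normal"
        assert table["log_ratio"].iloc[0] == -math.inf

    def test_log_ratio_sign_matches_call(self):
        model = self.make_model()
        rng = np.random.default_rng(17)
        z = rng.standard_normal((8, 200)) * 3
        table = tx.classify(model, z)
        anomalous = table["call"] == "anomaly"
        assert (table.loc[anomalous, "log_ratio"] > 0).all()
        assert (table.loc[~anomalous, "log_ratio"] <= 0).all()


class TestFitDetector:
    def test_fit_and_score_pipeline(self, small_study, small_model):
        table = tx.score_samples(small_model, small_study["test"])
        assert len(table) == small_study["test"].n_samples
        assert set(table["call"]) <= {"normal", "anomaly"}
        # anomalies carry large off-subspace displacement: top scores are cancers
        top = table.nlargest(10, "score")
        assert (top["true_label"] == "cancer").all()

    def test_empirical_threshold_method(self, small_study):
        model = tx.fit_detector(
            small_study["train"], log=True, k=5, threshold_method="empirical"
        )
        z = tx.apply_standardizer(model.standardizer, small_study["train"])
        scores = tx.residue_score(model.loadings, z.to_numpy())
        expected = np.quantile(scores, 0.95)
        assert model.q_threshold == pytest.approx(expected, rel=1e-12)

    def test_self_scoring_false_alarm_rate_near_alpha(self, small_study, small_model):
        table = tx.score_samples(small_model, small_study["train"])
        fraction = (table["call"] == "anomaly").mean()
        assert fraction < 2.5 * small_model.alpha

    def test_unknown_threshold_method(self, small_study):
        with pytest.raises(tx.DetectorError, match="threshold_method"):
            tx.fit_detector(small_study["train"], threshold_method="magic")

    def test_score_with_intersect_logs_reduced_space(self, small_study, small_model):
        test = small_study["test"]
        reduced = tx.ExpressionMatrix(
            gene_ids=test.gene_ids[:-5],
            sample_ids=test.sample_ids,
            values=test.values[:-5, :],
            labels=test.labels,
        )
        with pytest.raises(tx.PreprocessError):
            tx.score_samples(small_model, reduced)
        table = tx.score_samples(small_model, reduced, on_missing="intersect")
        assert len(table) == test.n_samples
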
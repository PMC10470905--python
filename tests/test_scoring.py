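import numpy as np
import pytest
import scipy.stats

from streak.scoring import (
    GammaFitError,
    GammaParams,
    TechnicalVariances,
    fit_gamma_mle,
    modified_mahalanobis,
    permute_within_columns,
    score_receptor,
    technical_variance,
)
from streak.types import ReconstructedMatrix, ValidationError


def _recon(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{j}" for j in range(values.shape[1])]
    return ReconstructedMatrix(values, [f"c{i}" for i in range(values.shape[0])],
                               ids, rank_used=min(values.shape))


class TestTechnicalVariance:
    def test_unbiased_sample_variance(self):
        tv = technical_variance(_recon([[0.0, 1.0], [2.0, 1.0]]), ["g0", "g1"])
        assert tv.variances[0] == pytest.approx(2.0)  # ((0-1)^2+(2-1)^2)/1
        assert tv.variances[1] == 0.0

    def test_invariant_to_cell_order(self, rng):
        vals = rng.random((10, 3))
        a = technical_variance(_recon(vals), ["g0", "g2"])
        b = technical_variance(_recon(vals[::-1]), ["g0", "g2"])
        np.testing.assert_allclose(a.variances, b.variances)

    def test_unknown_gene_rejected(self, rng):
        with pytest.raises(ValidationError, match="gX"):
            technical_variance(_recon(rng.random((4, 2))), ["gX"])


class TestModifiedMahalanobis:
    def test_unit_example(self):
        tv = TechnicalVariances(np.ones(2), ["g0", "g1"])
        d = modified_mahalanobis(np.array([[1.0, 2.0]]), tv, np.ones(2))
        assert d[0] == pytest.approx(5.0)

    def test_weight_scales_gene_contribution(self):
        tv = TechnicalVariances(np.array([2.0, 3.0]), ["g0", "g1"])
        x = np.array([[1.5, 0.0]])
        base = modified_mahalanobis(x, tv, np.array([1.0, 1.0]))[0]
        doubled = modified_mahalanobis(x, tv, np.array([2.0, 1.0]))[0]
        assert doubled == pytest.approx(2 * base)

    def test_matches_elementwise_loop(self, rng):
        x = rng.normal(size=(5, 3))
        var = rng.random(3) + 0.1
        w = rng.random(3) + 0.1
        tv = TechnicalVariances(var, ["g0", "g1", "g2"])
        fast = modified_mahalanobis(x, tv, w)
        for c in range(5):
            manual = sum(x[c, j] ** 2 / (var[j] / w[j]) for j in range(3))
            assert fast[c] == pytest.approx(manual, abs=1e-12)

    def test_all_zero_variance_rejected(self):
        tv = TechnicalVariances(np.zeros(2), ["g0", "g1"])
        with pytest.raises(ValidationError):
            modified_mahalanobis(np.ones((3, 2)), tv, np.ones(2))


class TestPermuteWithinColumns:
    def test_column_multisets_preserved(self, rng):
        m = rng.random((20, 4))
        p = permute_within_columns(m, seed=5)
        np.testing.assert_allclose(np.sort(p, axis=0), np.sort(m, axis=0))

    def test_seed_determinism(self, rng):
        m = rng.random((10, 3))
        np.testing.assert_array_equal(permute_within_columns(m, 7),
                                      permute_within_columns(m, 7))
        assert not np.array_equal(permute_within_columns(m, 7),
                                  permute_within_columns(m, 8))

    def test_single_row_unchanged(self):
        m = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(permute_within_columns(m, 0), m)


class TestFitGammaMle:
    def test_parameter_recovery(self):
        x = np.random.default_rng(12345).gamma(shape=2.0, scale=1 / 3.0, size=50_000)
        params = fit_gamma_mle(x)
        assert 1.94 <= params.shape <= 2.06
        assert 2.9 <= params.rate <= 3.1

    def test_constant_vector_degenerate(self):
        with pytest.raises(GammaFitError):
            fit_gamma_mle(np.full(10, 3.3))

    def test_zeros_dropped(self):
        x = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        params = fit_gamma_mle(x)
        assert params.n_used == 3

    def test_small_sample_matches_numeric_mle_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        params = fit_gamma_mle(x)
        shape_ref, _, scale_ref = scipy.stats.gamma.fit(x, floc=0)
        assert params.shape == pytest.approx(shape_ref, abs=1e-6)
        assert params.rate == pytest.approx(1 / scale_ref, abs=1e-6)
        # stationarity of the profile log-likelihood at the fitted shape
        def nll(a):
            return -scipy.stats.gamma.logpdf(x, a=a, scale=x.mean() / a).sum()
        assert nll(params.shape) <= min(nll(params.shape * 1.001), nll(params.shape * 0.999))


class TestScoreReceptor:
    def _setup(self, rng, n=300, g=4):
        vals = rng.lognormal(0, 1, size=(n, g))
        vals[0, :] = 0.0  # one cell with no expression of the set
        ids = [f"g{j}" for j in range(g)]
        recon = _recon(vals, ids)
        gene_set = [(f"g{j}", 1.0 - 0.1 * j) for j in range(g)]
        return recon, gene_set

    def test_zero_cell_gets_zero_score(self, rng):
        recon, gene_set = self._setup(rng)
        dist, scores, params = score_receptor(recon, gene_set, seed=3)
        assert dist[0] == 0.0 and scores[0] == 0.0
        assert params is not None

    def test_scores_bounded_and_monotone_in_distance(self, rng):
        recon, gene_set = self._setup(rng)
        dist, scores, _ = score_receptor(recon, gene_set, seed=3)
        assert scores.min() >= 0 and scores.max() <= 1
        order = np.argsort(dist)
        assert np.all(np.diff(scores[order]) >= -1e-12)

    def test_exponential_cdf_closed_form(self):
        # shape 1, rate 1 is the unit exponential: CDF(ln 2) = 1/2
        params = GammaParams(1.0, 1.0, 10)
        assert scipy.stats.gamma.cdf(np.log(2), a=params.shape,
                                     scale=1 / params.rate) == pytest.approx(0.5)

    def test_direct_null_mode(self, rng):
        recon, gene_set = self._setup(rng)
        _, scores, params = score_receptor(recon, gene_set, null_mode="direct", seed=3)
        assert params is not None and 0 <= scores.min() and scores.max() <= 1

    def test_weight_rescaling_preserves_ranking(self, rng):
        recon, gene_set = self._setup(rng)
        d1, _, _ = score_receptor(recon, gene_set, seed=3)
        scaled = [(g, 3.0 * w) for g, w in gene_set]
        d2, _, _ = score_receptor(recon, scaled, seed=3)
        np.testing.assert_allclose(d2, 3.0 * d1, rtol=1e-10)

    def test_missing_genes_listed(self, rng):
        recon, _ = self._setup(rng)
        with pytest.raises(ValidationError, match="gX"):
            score_receptor(recon, [("gX", 1.0)], seed=0)

    def test_degenerate_calibration_falls_back(self, rng, caplog):
        # two distinct values only -> distances on the permuted copy are constant
        vals = np.ones((6, 1))
        recon = _recon(vals, ["g0"])
        recon.values[0, 0] = 0.0
        with caplog.at_level("WARNING"):
            dist, scores, params = score_receptor(recon, [("g0", 1.0)], seed=0)
        assert params is None
        assert set(np.round(scores, 12)) <= {0.0, 1.0}
        assert any("degenerate" in r.message for r in caplog.records)

    def test_null_scores_near_uniform(self):
        """On i.i.d. columns the permutation-calibrated scores are ~Uniform(0,1).

        Half-normal expression noise: weighted sums of squares are then close
        to gamma, the regime the calibration assumes.
        """
        rng = np.random.default_rng(99)
        vals = np.abs(rng.normal(size=(5000, 10)))
        recon = _recon(vals, [f"g{j}" for j in range(10)])
        gene_set = [(f"g{j}", 0.5 + 0.05 * j) for j in range(10)]
        _, scores, _ = score_receptor(recon, gene_set, seed=11)
        ks = scipy.stats.kstest(scores, "uniform").statistic
        assert ks < 0.05
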
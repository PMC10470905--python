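import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from streak.preprocess import clr_normalize, log_normalize, rrr_reconstruct, select_rank
from streak.types import CountMatrix, NormalizedMatrix, ValidationError


def _cm(values, modality="rna"):
    values = np.asarray(values, dtype=float)
    return CountMatrix(values,
                       [f"c{i}" for i in range(values.shape[0])],
                       [f"g{j}" for j in range(values.shape[1])], modality)


class TestLogNormalize:
    def test_formula(self):
        # counts [1,1,2] in one cell: total 4, count-1 gene -> ln(1 + 1e4/4)
        norm = log_normalize(_cm([[1, 1, 2]]))
        assert norm.values[0, 0] == pytest.approx(np.log(2501), abs=1e-4)
        assert norm.values[0, 0] == pytest.approx(7.8245, abs=1e-4)

    def test_zero_count_maps_to_zero(self):
        norm = log_normalize(_cm([[0, 5]]))
        assert norm.values[0, 0] == 0.0

    def test_scale_invariance_within_cell(self, rng):
        counts = rng.integers(0, 20, size=(6, 8)).astype(float) + 1
        doubled = counts.copy()
        doubled[2] *= 2
        np.testing.assert_allclose(
            log_normalize(_cm(counts)).values[2],
            log_normalize(_cm(doubled)).values[2],
        )

    def test_monotone_within_cell(self, rng):
        counts = rng.integers(0, 50, size=(1, 30)).astype(float)
        counts[0, 0] = 1
        norm = log_normalize(_cm(counts)).values[0]
        order = np.argsort(counts[0])
        assert np.all(np.diff(norm[order]) >= 0)

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValidationError, match="c1"):
            log_normalize(_cm([[1, 1], [0, 0]]))


class TestClrNormalize:
    def test_hand_example(self):
        norm = clr_normalize(_cm([[0, 1, 3]], "adt"))
        np.testing.assert_allclose(norm.values[0], [-np.log(2), 0.0, np.log(2)], atol=1e-10)
        np.testing.assert_allclose(norm.values[0], [-0.6931, 0.0, 0.6931], atol=1e-4)

    def test_constant_vector_maps_to_zero(self):
        norm = clr_normalize(_cm([[4, 4, 4]], "adt"))
        np.testing.assert_allclose(norm.values, 0.0, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float64, (5, 4), elements=st.floats(0, 1e4)))
    def test_centering_along_margin(self, counts):
        cm = CountMatrix(counts, [f"c{i}" for i in range(5)],
                         [f"a{j}" for j in range(4)], "adt")
        assert np.abs(clr_normalize(cm, "per_cell").values.mean(axis=1)).max() < 1e-10
        assert np.abs(clr_normalize(cm, "per_feature").values.mean(axis=0)).max() < 1e-10


def _norm(values):
    # "clr" labelling: plain real-valued matrices (negatives allowed)
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(values, [f"c{i}" for i in range(values.shape[0])],
                            [f"g{j}" for j in range(values.shape[1])], "clr")


class TestSelectRank:
    def test_rank_one_matrix_collapses(self, rng):
        m = np.outer(rng.random(50), rng.random(30))
        sel = select_rank(_norm(m), max_rank=10, seed=0)
        assert sel.selected_rank <= 3
        assert np.all(sel.candidate_sds[2:] < 1e-8 * sel.candidate_sds[0])

    def test_planted_components_recovered(self):
        """Five strong orthogonal components over weak i.i.d. noise: the elbow
        lands just past the planted signal (checked against an exact-SVD
        spectrum showing the gap after component 5)."""
        rng = np.random.default_rng(42)
        u = np.linalg.qr(rng.normal(size=(500, 5)))[0]
        v = np.linalg.qr(rng.normal(size=(200, 5)))[0]
        amps = np.array([100.0, 80.0, 60.0, 45.0, 30.0])
        m = (u * amps) @ v.T + rng.normal(scale=0.5, size=(500, 200))
        exact = np.linalg.svd(m, compute_uv=False)
        assert exact[4] / exact[5] > 1.3  # spectrum gap after the 5 components
        sel = select_rank(_norm(m), max_rank=30, seed=1)
        assert 4 <= sel.selected_rank <= 15

    def test_candidate_sds_non_increasing(self, rng):
        sel = select_rank(_norm(rng.random((40, 25))), max_rank=20, seed=3)
        assert np.all(np.diff(sel.candidate_sds) <= 1e-12)

    def test_max_rank_bound(self, rng):
        with pytest.raises(ValidationError):
            select_rank(_norm(rng.random((10, 5))), max_rank=6, seed=0)


class TestRrrReconstruct:
    def test_full_rank_identity(self, rng):
        m = rng.random((12, 8))
        recon = rrr_reconstruct(_norm(m), rank=8, seed=0, clamp=False)
        rel = np.linalg.norm(recon.values - m) / np.linalg.norm(m)
        assert rel < 1e-8

    def test_rank_one_input_exact(self, rng):
        m = np.outer(rng.random(10), rng.random(6))
        recon = rrr_reconstruct(_norm(m), rank=1, seed=0, clamp=False)
        np.testing.assert_allclose(recon.values, m, atol=1e-10)

    @pytest.mark.parametrize("k", [1, 5, 10])
    def test_eckart_young_tail_energy(self, rng, k):
        m = rng.normal(size=(30, 20))
        recon = rrr_reconstruct(_norm(m), rank=k, seed=0, clamp=False)
        err2 = np.linalg.norm(m - recon.values) ** 2
        tail2 = (np.linalg.svd(m, compute_uv=False)[k:] ** 2).sum()
        assert err2 == pytest.approx(tail2, rel=1e-6)

    def test_error_non_increasing_in_rank(self, rng):
        m = rng.normal(size=(15, 10))
        errs = [np.linalg.norm(m - rrr_reconstruct(_norm(m), r, seed=0, clamp=False).values)
                for r in range(1, 11)]
        assert np.all(np.diff(errs) <= 1e-9)

    def test_clamp_touches_only_negative_entries(self, rng):
        m = rng.normal(size=(20, 10))
        raw = rrr_reconstruct(_norm(m), 3, seed=0, clamp=False)
        clamped = rrr_reconstruct(_norm(m), 3, seed=0, clamp=True)
        changed = clamped.values != raw.values
        assert np.all(raw.values[changed] < 0)        # only negatives touched
        assert np.all(clamped.values[changed] == 0.0)  # and raised exactly to 0
        assert clamped.clamp_count == int((raw.values < 0).sum())
        assert np.all(clamped.values >= 0)

    def test_rank_out_of_bounds(self, rng):
        with pytest.raises(ValidationError):
            rrr_reconstruct(_norm(rng.random((5, 4))), rank=5, seed=0)
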
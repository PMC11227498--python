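import numpy as np
import pandas as pd
import pytest

from ihcsub.errors import (
    FieldRangeError,
    MissingGeneError,
    TransformStateError,
)
from ihcsub.expression import (
    CUSTOM5,
    ExpressionMatrix,
    GeneSignature,
    TransformState,
    cpm_log2,
    custom5_score,
    dichotomize_scores,
    rank_log2fc,
    read_expression,
    signature_score,
    write_expression,
    zscore_genes,
)

FIVE = ["TP63", "KRT5", "KRT6A", "GATA6", "HNF4A"]


def _matrix(values, genes=None, samples=None, state=TransformState.COUNTS):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), state=state)


def _z_matrix(values, genes=None, samples=None):
    return _matrix(values, genes, samples, state=TransformState.ZSCORE)


class TestStateMachine:
    def test_zscore_rejects_counts(self):
        with pytest.raises(TransformStateError):
            zscore_genes(_matrix([[1, 2], [3, 4]]))

    def test_cpm_rejects_log(self):
        m = cpm_log2(_matrix([[1, 2], [3, 4]]))
        with pytest.raises(TransformStateError):
            cpm_log2(m)

    def test_signature_rejects_log_cpm(self):
        m = cpm_log2(_matrix([[1, 2], [3, 4]]))
        with pytest.raises(TransformStateError):
            signature_score(m, CUSTOM5)

    def test_rank_log2fc_rejects_zscore(self):
        z = zscore_genes(cpm_log2(_matrix([[1, 2], [3, 4]])))
        with pytest.raises(TransformStateError):
            rank_log2fc(z, {"S0": "HIGH", "S1": "LOW"})


class TestCpmLog2:
    def test_single_gene_full_library(self):
        m = cpm_log2(_matrix([[100.0]], samples=["only"]))
        assert m.values.iloc[0, 0] == pytest.approx(np.log2(1e6 + 1))

    def test_zero_count_with_unit_pseudocount(self):
        m = cpm_log2(_matrix([[0, 5], [10, 5]]))
        assert m.values.iloc[0, 0] == 0.0

    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, size=(30, 5)).astype(float)
        counts[0] += 1  # avoid zero library
        m = _matrix(counts)
        with np.errstate(divide="ignore"):
            cpm = 2.0 ** cpm_log2(m, pseudocount=0).values
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        with pytest.raises(FieldRangeError):
            cpm_log2(_matrix([[0, 1], [0, 2]]))


class TestZscore:
    def test_constant_row_maps_to_zeros(self):
        z = zscore_genes(_matrix([[5, 5, 5], [1, 2, 3]],
                                 state=TransformState.LOG_CPM))
        assert np.all(z.values.iloc[0].to_numpy() == 0)

    def test_rows_have_mean0_sd1(self):
        rng = np.random.default_rng(1)
        z = zscore_genes(_matrix(rng.normal(size=(10, 8)),
                                 state=TransformState.LOG_CPM))
        vals = z.values.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(vals.std(axis=1, ddof=1), 1)

    def test_invariant_to_per_gene_affine_shift(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 7))
        shifted = base + rng.normal(size=(6, 1))
        z1 = zscore_genes(_matrix(base, state=TransformState.LOG_CPM))
        z2 = zscore_genes(_matrix(shifted, state=TransformState.LOG_CPM))
        assert np.allclose(z1.values.to_numpy(), z2.values.to_numpy())

    def test_single_sample_rejected(self):
        with pytest.raises(FieldRangeError):
            zscore_genes(_matrix([[1.0]], state=TransformState.LOG_CPM))


class TestSignatureScore:
    def test_all_zero_gives_zero(self):
        z = _z_matrix(np.zeros((5, 3)), genes=FIVE)
        assert np.all(signature_score(z, CUSTOM5).scores == 0)

    def test_up_only_arithmetic(self):
        sig = GeneSignature("up3", up_genes=("A", "B", "C"))
        z = _z_matrix(np.ones((3, 2)), genes=["A", "B", "C"])
        assert np.all(signature_score(z, sig).scores == 3)

    def test_antisymmetric_under_up_down_swap(self):
        rng = np.random.default_rng(3)
        z = _z_matrix(rng.normal(size=(4, 5)), genes=["A", "B", "C", "D"])
        fwd = GeneSignature("f", up_genes=("A", "B"), down_genes=("C", "D"))
        rev = GeneSignature("r", up_genes=("C", "D"), down_genes=("A", "B"))
        assert np.allclose(signature_score(z, fwd).scores,
                           -signature_score(z, rev).scores)

    def test_missing_genes_skipped_with_warning(self):
        sig = GeneSignature("s", up_genes=("A", "NOPE"))
        z = _z_matrix(np.ones((1, 2)), genes=["A"])
        with pytest.warns(UserWarning):
            scores = signature_score(z, sig).scores
        assert np.all(scores == 1)

    def test_no_genes_present_is_error(self):
        sig = GeneSignature("s", up_genes=("NOPE",))
        z = _z_matrix(np.ones((1, 2)), genes=["A"])
        with pytest.raises(MissingGeneError):
            signature_score(z, sig)


class TestCustom5:
    def test_fixed_profile(self):
        vals = np.array([[1.0], [1.0], [1.0], [0.0], [0.0]])
        z = _z_matrix(vals, genes=FIVE, samples=["s"])
        assert custom5_score(z).scores[0] == pytest.approx(3.0)

    def test_equals_generic_signature_score(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 500, size=(40, 12)).astype(float)
        genes = FIVE + [f"G{i}" for i in range(35)]
        z = zscore_genes(cpm_log2(_matrix(counts, genes=genes)))
        assert np.array_equal(custom5_score(z).scores,
                              signature_score(z, CUSTOM5).scores)

    def test_case_insensitive_match(self):
        vals = np.zeros((5, 2))
        z = _z_matrix(vals, genes=["tp63", "Krt5", "KRT6a", "gata6", "HNF4a"])
        assert np.all(custom5_score(z).scores == 0)

    def test_absent_gene_is_error(self):
        z = _z_matrix(np.zeros((4, 2)), genes=FIVE[:4])
        with pytest.raises(MissingGeneError):
            custom5_score(z)


class TestDichotomize:
    def test_median_tie_rule(self):
        from ihcsub.expression import ScoreVector

        sv = ScoreVector("s", ("a", "b", "c"), np.array([-1.0, 0.0, 2.0]))
        assert dichotomize_scores(sv) == {"a": "LOW", "b": "LOW", "c": "HIGH"}

    def test_even_symmetric_split(self):
        from ihcsub.expression import ScoreVector

        sv = ScoreVector("s", tuple("abcd"), np.array([-2.0, -1.0, 1.0, 2.0]))
        labels = dichotomize_scores(sv)
        assert sorted(labels.values()).count("HIGH") == 2

    def test_monotone_transform_invariance(self):
        from ihcsub.expression import ScoreVector

        rng = np.random.default_rng(5)
        scores = rng.normal(size=9)
        sv1 = ScoreVector("s", tuple(f"x{i}" for i in range(9)), scores)
        sv2 = ScoreVector("s", tuple(f"x{i}" for i in range(9)),
                          np.exp(scores))
        assert dichotomize_scores(sv1) == dichotomize_scores(sv2)

    def test_degenerate_all_low_with_warning(self):
        from ihcsub.expression import ScoreVector

        sv = ScoreVector("s", ("a", "b"), np.zeros(2))
        with pytest.warns(UserWarning):
            labels = dichotomize_scores(sv)
        assert set(labels.values()) == {"LOW"}


class TestRankLog2FC:
    def test_identical_groups_zero(self):
        m = _matrix([[1.0, 1.0], [2.0, 2.0]], state=TransformState.LOG_CPM)
        out = rank_log2fc(m, {"S0": "HIGH", "S1": "LOW"})
        assert np.all(out["log2fc"].to_numpy() == 0)

    def test_shifted_gene_fc_one(self):
        m = _matrix([[3.0, 2.0], [1.0, 1.0]], state=TransformState.LOG_CPM)
        out = rank_log2fc(m, {"S0": "HIGH", "S1": "LOW"})
        assert out.iloc[0]["gene"] == "G0"
        assert out.iloc[0]["log2fc"] == pytest.approx(1.0)

    def test_sorted_descending(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(15, 6)), state=TransformState.LOG_CPM)
        groups = {f"S{i}": ("HIGH" if i < 3 else "LOW") for i in range(6)}
        out = rank_log2fc(m, groups)
        fc = out["log2fc"].to_numpy()
        assert np.all(np.diff(fc) <= 1e-12)

    def test_empty_group_rejected(self):
        m = _matrix([[1.0, 2.0]], state=TransformState.LOG_CPM)
        with pytest.raises(FieldRangeError):
            rank_log2fc(m, {"S0": "HIGH", "S1": "HIGH"})


class TestIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        m = _matrix(rng.integers(0, 50, size=(8, 4)).astype(float))
        p = tmp_path / "m.tsv"
        write_expression(m, p)
        again = read_expression(p)
        assert np.allclose(m.values.to_numpy(), again.values.to_numpy())
        assert list(m.values.index) == list(again.values.index)
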
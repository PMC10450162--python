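import numpy as np
import pytest
from hypothesis import given, strategies as st

from antisense_pairs.diffexpr import (
    CountMatrix,
    DiffExprError,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    read_count_matrix,
    size_factors,
)
from conftest import make_count_matrix


def _nb_counts(rng, mu, alpha, shape):
    if alpha == 0:
        return rng.poisson(mu, size=shape)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=shape)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_count_matrix([[10, 10], [3, 3], [100, 100]])
        np.testing.assert_allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        """sample2 = 2 x sample1 -> factors (1/sqrt(2), sqrt(2))."""
        base = np.array([[4], [10], [25], [7]])
        cm = make_count_matrix(np.hstack([base, 2 * base]))
        np.testing.assert_allclose(
            size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_single_sample_factor_is_one(self):
        cm = CountMatrix(["f0", "f1"], ["s"], np.array([[5], [9]]), {"s": "control"})
        np.testing.assert_allclose(size_factors(cm), [1.0])

    def test_error_when_no_all_positive_feature(self):
        cm = make_count_matrix([[0, 5], [5, 0]])
        with pytest.raises(DiffExprError, match="positive"):
            size_factors(cm)

    def test_scaling_one_sample_shifts_factors_by_shared_geomean(self):
        """Multiplying sample j by integer c multiplies s_j by c times the
        common factor c^(-1/n) that all samples share."""
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(50, 4)) + 1
        cm = make_count_matrix(counts)
        s = size_factors(cm)
        c = 3
        scaled = counts.copy()
        scaled[:, 1] *= c
        s2 = size_factors(make_count_matrix(scaled))
        shared = c ** (-1 / 4)
        expect = s * shared
        expect[1] = s[1] * c * shared
        np.testing.assert_allclose(s2, expect, rtol=1e-12)


class TestDispersion:
    def test_poisson_counts_hit_the_floor(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000, size=(400, 20))
        cm = make_count_matrix(counts, 10, 10)
        alpha, untestable = estimate_dispersion(cm, size_factors(cm))
        assert np.median(alpha) < 0.01
        assert not untestable.any()

    def test_constant_counts_floor(self):
        cm = make_count_matrix([[7, 7, 9, 9]], 2, 2)
        alpha, _ = estimate_dispersion(cm, np.ones(4))
        # zero within-condition variance -> (v - m)/m^2 < 0 -> floored
        assert alpha[0] == pytest.approx(1e-8)

    def test_nb_dispersion_recovered(self):
        """MoM consistency: alpha=0.2 at mean 500, 50 reps per condition."""
        rng = np.random.default_rng(1)
        counts = _nb_counts(rng, 500.0, 0.2, (300, 100))
        cm = make_count_matrix(counts, 50, 50)
        alpha, _ = estimate_dispersion(cm, np.ones(100))
        assert 0.15 <= np.median(alpha) <= 0.25

    def test_all_zero_feature_flagged_untestable(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        cm = make_count_matrix(counts, 2, 2)
        alpha, untestable = estimate_dispersion(cm, np.ones(4))
        assert untestable.tolist() == [True, False]


class TestWald:
    def test_identical_conditions_null_result(self):
        counts = np.array([[10, 20, 10, 20], [5, 5, 5, 5]])
        cm = make_count_matrix(counts, 2, 2)
        de = nb_wald_test(cm, sf=np.ones(4))
        np.testing.assert_allclose(de["log2fc"], 0.0)
        np.testing.assert_allclose(de["wald_z"], 0.0)
        np.testing.assert_allclose(de["pvalue"], 1.0)

    def test_all_zero_feature_untestable(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        cm = make_count_matrix(counts, 2, 2)
        de = nb_wald_test(cm, sf=np.ones(4))
        assert de.loc[0, "untestable"]
        assert de.loc[0, "log2fc"] == 0.0
        assert de.loc[0, "pvalue"] == 1.0

    def test_planted_log2fc_recovered(self):
        """Planted effect +1 log2 unit, 6v6 at mean 500: estimate within 5%."""
        rng = np.random.default_rng(2)
        n = 2000
        ctrl = _nb_counts(rng, 500.0, 0.05, (n, 6))
        trt = _nb_counts(rng, 1000.0, 0.05, (n, 6))
        cm = make_count_matrix(np.hstack([ctrl, trt]), 6, 6)
        de = nb_wald_test(cm, sf=np.ones(12))
        assert abs(de["log2fc"].mean() - 1.0) <= 0.05

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        counts = _nb_counts(rng, 200.0, 0.1, (100, 8))
        cm = make_count_matrix(counts, 4, 4)
        de = nb_wald_test(cm)
        flipped = {
            s: ("treatment" if c == "control" else "control")
            for s, c in cm.condition.items()
        }
        cm2 = CountMatrix(cm.feature_ids, cm.sample_ids, cm.counts, flipped)
        de2 = nb_wald_test(cm2)
        np.testing.assert_allclose(de2["log2fc"], -de["log2fc"], rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(de2["pvalue"], de["pvalue"], rtol=1e-10)

    def test_degenerate_design_rejected(self):
        cm = CountMatrix(
            ["f0"], ["a", "b", "c"], np.array([[1, 2, 3]]),
            {"a": "control", "b": "treatment", "c": "treatment"},
        )
        with pytest.raises(DiffExprError, match="control"):
            nb_wald_test(cm)

    def test_results_stable_under_renormalized_scaling(self):
        """Integer-rescaling one sample changes counts but, after the size
        factors absorb it, leaves log2FC and p-values essentially unchanged
        (the fixed pseudocount breaks exact equality at O(c0/mu))."""
        rng = np.random.default_rng(6)
        counts = _nb_counts(rng, 800.0, 0.05, (200, 8))
        cm = make_count_matrix(counts, 4, 4)
        de = nb_wald_test(cm)
        scaled = counts.copy()
        scaled[:, 2] *= 4
        de2 = nb_wald_test(make_count_matrix(scaled, 4, 4))
        np.testing.assert_allclose(de2["log2fc"], de["log2fc"], atol=2e-3)
        np.testing.assert_allclose(de2["pvalue"], de["pvalue"], rtol=0.02, atol=2e-3)


class TestBH:
    def test_three_pvalue_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffExprError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(DiffExprError):
            bh_adjust([-0.1])

    def test_qvalues_dominate_pvalues(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
        st.integers(min_value=0, max_value=19),
        st.floats(min_value=0, max_value=1),
    )
    def test_monotone_in_each_pvalue(self, pvals, idx, bump):
        """Increasing any single p-value never decreases any q-value."""
        idx = idx % len(pvals)
        bumped = list(pvals)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        q0 = bh_adjust(pvals)
        q1 = bh_adjust(bumped)
        assert (q1 >= q0 - 1e-12).all()


def test_count_matrix_io_round_trip(tmp_path):
    counts = np.array([[1, 2, 3, 4], [5, 6, 7, 8]])
    cm = make_count_matrix(counts, 2, 2)
    cpath = tmp_path / "counts.tsv"
    spath = tmp_path / "samples.tsv"
    with open(cpath, "w") as fh:
        fh.write("feature_id\t" + "\t".join(cm.sample_ids) + "\n")
        for fid, row in zip(cm.feature_ids, counts):
            fh.write(fid + "\t" + "\t".join(map(str, row)) + "\n")
    with open(spath, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s in cm.sample_ids:
            fh.write(f"{s}\t{cm.condition[s]}\n")
    back = read_count_matrix(cpath, spath)
    assert back.feature_ids == cm.feature_ids
    assert back.sample_ids == cm.sample_ids
    np.testing.assert_array_equal(back.counts, counts)


def test_negative_and_fractional_counts_rejected():
    with pytest.raises(DiffExprError):
        make_count_matrix([[-1, 2], [3, 4]])
    with pytest.raises(DiffExprError):
        make_count_matrix([[0.5, 2], [3, 4]])


def test_agrees_with_deseq2_reference_on_shared_model():
    """Independent cross-check: on a well-behaved simulated dataset the
    in-package Wald log2FCs should track pydeseq2's closely (both model NB
    counts with median-of-ratios normalization; estimators differ, so
    agreement is correlation-level, not bitwise)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    import pandas as pd
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(9)
    n = 200
    lfc = rng.normal(0, 1, n)
    mu = rng.lognormal(6, 0.5, n)
    ctrl = _nb_counts(rng, np.tile(mu[:, None], (1, 4)), 0.05, (n, 4))
    trt = _nb_counts(rng, np.tile((mu * 2.0**lfc)[:, None], (1, 4)), 0.05, (n, 4))
    cm = make_count_matrix(np.hstack([ctrl, trt]), 4, 4)
    ours = nb_wald_test(cm)

    meta = pd.DataFrame(
        {"condition": [cm.condition[s] for s in cm.sample_ids]}, index=cm.sample_ids
    )
    dds = DeseqDataSet(
        counts=pd.DataFrame(cm.counts.T, index=cm.sample_ids, columns=cm.feature_ids),
        metadata=meta,
        design="~condition",
        quiet=True,
    )
    dds.deseq2()
    res = DeseqStats(dds, contrast=["condition", "treatment", "control"], quiet=True)
    res.summary()
    theirs = res.results_df["log2FoldChange"].reindex(cm.feature_ids).to_numpy()

    r = np.corrcoef(ours["log2fc"], theirs)[0, 1]
    assert r > 0.98
    assert np.median(np.abs(ours["log2fc"].to_numpy() - theirs)) < 0.1
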
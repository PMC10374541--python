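import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diallelgs import (
    DataError,
    MarkerPanel,
    QCError,
    code_and_standardize,
    code_markers,
    drop_zero_dominance,
    enumerate_half_diallel,
    filter_markers,
    impute_major_allele,
    standardize,
    synthesize_hybrids,
)
from diallelgs.markers import HYBRID, PARENTAL_INBRED


def toy_panel():
    """20 inbreds x 5 markers: marker m3 is 50% missing, m5 has MAF 0.025."""
    n = 20
    common = np.tile([0.0, 2.0], n // 2)  # MAF 0.5
    m3 = common.copy()
    m3[:10] = np.nan
    m5 = np.zeros(n)
    m5[0] = 1.0  # single het: counted-allele freq 1/40
    dosages = np.column_stack([common, common, m3, common, m5])
    ids = [f"I{i}" for i in range(n)]
    return MarkerPanel(ids, ["m1", "m2", "m3", "m4", "m5"], dosages)


class TestFilterMarkers:
    def test_toy_panel_removals_by_first_failing_rule(self):
        panel, report = filter_markers(toy_panel(), 0.05, 0.05)
        assert panel.marker_ids == ["m1", "m2", "m4"]
        assert report.n_removed_missing == 1
        assert report.n_removed_maf == 1
        assert report.n_retained == 3
        assert report.n_input_markers == 5
        assert report.thresholds == (0.05, 0.05)

    def test_all_pass_is_identity(self):
        panel = toy_panel().subset_markers(np.array([True, True, False, True, False]))
        out, report = filter_markers(panel, 0.05, 0.05)
        assert out.marker_ids == panel.marker_ids
        np.testing.assert_array_equal(out.dosages, panel.dosages)
        assert report.n_removed_missing == report.n_removed_maf == 0

    def test_all_removed_names_thresholds(self):
        panel = toy_panel().subset_markers(np.array([False, False, True, False, True]))
        with pytest.raises(QCError, match="0.05"):
            filter_markers(panel, 0.05, 0.05)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(DataError):
            filter_markers(toy_panel(), -0.1, 0.05)


class TestImputeMajorAllele:
    def test_major_homozygote_fills_missing(self):
        panel = MarkerPanel(
            ["a", "b", "c", "d", "e"], ["m"],
            np.array([[2.0], [2.0], [2.0], [0.0], [np.nan]]),
        )
        out = impute_major_allele(panel)
        assert out.dosages[4, 0] == 2.0

    def test_no_missing_unchanged(self):
        panel = MarkerPanel(["a", "b"], ["m"], np.array([[0.0], [2.0]]))
        out = impute_major_allele(panel)
        np.testing.assert_array_equal(out.dosages, panel.dosages)

    def test_tie_resolves_to_zero_with_warning(self):
        panel = MarkerPanel(
            ["a", "b", "c", "d", "e"], ["m"],
            np.array([[0.0], [0.0], [2.0], [2.0], [np.nan]]),
        )
        with pytest.warns(UserWarning, match="tie"):
            out = impute_major_allele(panel)
        assert out.dosages[4, 0] == 0.0

    def test_all_missing_marker_is_error(self):
        panel = MarkerPanel(["a", "b"], ["m1", "m2"],
                            np.array([[0.0, np.nan], [2.0, np.nan]]))
        with pytest.raises(DataError, match="m2"):
            impute_major_allele(panel)


class TestHalfDiallel:
    @pytest.mark.parametrize("n_parents,n_pairs", [(142, 10011), (24, 276), (2, 1)])
    def test_pair_counts(self, n_parents, n_pairs):
        frame = enumerate_half_diallel([f"P{i}" for i in range(n_parents)])
        assert frame.N1 == n_pairs

    @given(st.integers(2, 200))
    def test_count_formula(self, n0):
        frame = enumerate_half_diallel([f"P{i}" for i in range(n0)])
        assert frame.N1 == n0 * (n0 - 1) // 2
        assert all(i < j for i, j in frame.pairs)
        assert len(set(frame.pairs)) == frame.N1

    def test_duplicate_parents_rejected(self):
        with pytest.raises(DataError):
            enumerate_half_diallel(["A", "B", "A"])


class TestSynthesizeHybrids:
    def test_dosage_midpoint(self):
        parents = MarkerPanel(
            ["A", "B"], ["m1", "m2", "m3"],
            np.array([[2.0, 0.0, 0.0], [2.0, 2.0, 0.0]]),
        )
        frame = enumerate_half_diallel(["A", "B"])
        hyb = synthesize_hybrids(parents, frame)
        np.testing.assert_array_equal(hyb.dosages, [[2.0, 1.0, 0.0]])
        assert hyb.ploidy_role == HYBRID

    def test_symmetric_in_parent_order(self):
        rng = np.random.default_rng(0)
        dos = rng.choice([0.0, 2.0], size=(4, 30))
        fwd = MarkerPanel(["A", "B", "C", "D"], [f"m{i}" for i in range(30)], dos)
        rev = MarkerPanel(["D", "C", "B", "A"], [f"m{i}" for i in range(30)], dos[::-1])
        frame = enumerate_half_diallel(["A", "B", "C", "D"])
        h1 = synthesize_hybrids(fwd, frame)
        h2 = synthesize_hybrids(rev, frame)
        np.testing.assert_array_equal(h1.dosages, h2.dosages)
        assert h1.individual_ids == h2.individual_ids

    def test_heterozygous_parent_rejected_by_default(self):
        parents = MarkerPanel(["A", "B"], ["m"], np.array([[1.0], [2.0]]))
        frame = enumerate_half_diallel(["A", "B"])
        with pytest.raises(DataError, match="heterozygous"):
            synthesize_hybrids(parents, frame)

    def test_permissive_flag_imputes_heterozygotes(self):
        parents = MarkerPanel(
            ["A", "B", "C"], ["m"], np.array([[1.0], [2.0], [2.0]])
        )
        frame = enumerate_half_diallel(["A", "B", "C"])
        with pytest.warns(UserWarning):
            hyb = synthesize_hybrids(parents, frame, on_heterozygote="missing")
        # A's het call became the major homozygote (2), so all crosses are 2
        np.testing.assert_array_equal(hyb.dosages, [[2.0], [2.0], [2.0]])


class TestCoding:
    def test_heterozygote_scores(self):
        panel = MarkerPanel(["a", "b", "c"], ["m"],
                            np.array([[0.0], [1.0], [2.0]]), HYBRID)
        A, D, _ = code_markers(panel)
        assert D[1, 0] == 1.0 and D[0, 0] == 0.0 and D[2, 0] == 0.0
        assert A[1, 0] == 0.0

    def test_minor_count_orientation(self):
        # counted-allele freq 3/10 < 0.5: dosage 2 is the minor homozygote
        panel = MarkerPanel(
            list("abcde"), ["m"],
            np.array([[2.0], [0.0], [0.0], [0.0], [1.0]]), HYBRID,
        )
        A, _, _ = code_markers(panel)
        assert A[0, 0] == -1.0  # minor homozygote
        assert A[1, 0] == 1.0  # major homozygote

    def test_all_homozygous_marker_has_zero_dominance(self):
        panel = MarkerPanel(["a", "b"], ["m"], np.array([[0.0], [2.0]]))
        _, D, _ = code_markers(panel)
        assert (D == 0).all()

    def test_missing_entries_rejected(self):
        panel = MarkerPanel(["a", "b"], ["m"], np.array([[np.nan], [2.0]]))
        with pytest.raises(DataError, match="impute"):
            code_markers(panel)

    def test_hybrid_additive_is_parental_midpoint(self, small_dataset):
        parents, frame = small_dataset.parents, small_dataset.frame
        hybrids = synthesize_hybrids(parents, frame)
        _, _, orient = code_markers(hybrids)
        A_par, _, _ = code_markers(parents, orientation=orient)
        A_hyb, _, _ = code_markers(hybrids, orientation=orient)
        for row, (i, j) in enumerate(frame.pairs):
            np.testing.assert_allclose(
                A_hyb[row], (A_par[i] + A_par[j]) / 2.0, atol=1e-12
            )


class TestZeroDominanceFilter:
    def test_no_heterozygote_column_removed(self):
        A = np.zeros((4, 3))
        D = np.array([[1.0, 0, 1], [0, 0, 0], [0, 0, 1], [1, 0, 0]])
        A2, D2, ids, removed = drop_zero_dominance(A, D, ["m1", "m2", "m3"])
        assert ids == ["m1", "m3"]
        assert removed == 1
        assert A2.shape == D2.shape == (4, 2)

    def test_all_informative_unchanged(self):
        D = np.array([[1.0, 1.0], [0.0, 0.0]])
        _, _, ids, removed = drop_zero_dominance(np.zeros((2, 2)), D, ["m1", "m2"])
        assert removed == 0 and ids == ["m1", "m2"]

    def test_everything_removed_is_error(self):
        with pytest.raises(QCError):
            drop_zero_dominance(np.zeros((2, 1)), np.zeros((2, 1)), ["m1"])


class TestStandardize:
    def test_unit_variance_column_unchanged(self):
        A = np.array([[-1.0], [0.0], [1.0]])
        D = np.array([[0.0], [1.0], [0.0]])
        coded = standardize(A, D, ["m"])
        np.testing.assert_allclose(coded.X_A[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_dominance_column_hand_value(self):
        A = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        D = np.array([[0.0], [0.0], [1.0], [1.0]])
        coded = standardize(A, D, ["m"])
        sd = np.std([0, 0, 1, 1], ddof=1)  # sqrt(1/3)
        np.testing.assert_allclose(
            coded.X_D[:, 0], np.array([-0.5, -0.5, 0.5, 0.5]) / sd, atol=1e-12
        )

    def test_zero_variance_column_names_marker(self):
        A = np.array([[1.0], [1.0]])
        D = np.array([[0.0], [1.0]])
        with pytest.raises(QCError, match="m_const"):
            standardize(A, D, ["m_const"])

    def test_reference_rows_define_scale_for_all_rows(self, small_dataset):
        hybrids = synthesize_hybrids(small_dataset.parents, small_dataset.frame)
        ref = np.arange(20)
        coded, _ = code_and_standardize(hybrids, reference_rows=ref,
                                        drop_zero_variance=True)
        np.testing.assert_allclose(coded.X_A[ref].mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(coded.X_A[ref].std(axis=0, ddof=1), 1, atol=1e-10)
        np.testing.assert_allclose(coded.X_D[ref].mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(coded.X_D[ref].std(axis=0, ddof=1), 1, atol=1e-10)


def test_filter_then_impute_leaves_clean_panel():
    rng = np.random.default_rng(3)
    dos = rng.choice([0.0, 2.0], size=(30, 40), p=[0.3, 0.7])
    mask = rng.random(dos.shape) < 0.02
    dos[mask] = np.nan
    panel = MarkerPanel([f"I{i}" for i in range(30)],
                        [f"m{j}" for j in range(40)], dos)
    filtered, _ = filter_markers(panel, 0.05, 0.05)
    imputed = impute_major_allele(filtered)
    assert not np.isnan(imputed.dosages).any()
    assert (imputed.maf() >= 0.05).all()
    assert imputed.ploidy_role == PARENTAL_INBRED
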
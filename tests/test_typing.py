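import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kstest

from markertyper.marker_db import MarkerSet
from markertyper.preprocess import ExpressionMatrix, ValidationError
from markertyper.typing import (assign_types, average_score, bh_fdr,
                                build_templates, gsea_score, ntp_score)


def marker(cell_type, genes, label="Test.2020.Sim.TME"):
    return MarkerSet.from_label(label, cell_type, genes)


def scaled_matrix(vals, genes, cells):
    return ExpressionMatrix(np.asarray(vals, float), genes, cells, "scaled")


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------


def cosine_distance_oracle(x, template):
    """Brute-force (1 - cos)/2 with explicit loops."""
    num = sum(a * b for a, b in zip(x, template))
    nx = sum(a * a for a in x) ** 0.5
    nt = sum(b * b for b in template) ** 0.5
    return (1.0 - num / (nx * nt)) / 2.0


def es_oracle(metric, hit, weight):
    """Brute-force running-sum ES: rank descending, walk the list."""
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], i))
    n, n_hit = len(metric), sum(hit)
    denom = sum(abs(metric[i]) ** weight for i in order if hit[i])
    best, running = 0.0, 0.0
    for i in order:
        if hit[i]:
            running += (abs(metric[i]) ** weight) / denom if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------


class TestBuildTemplates:
    def test_disjoint_sets_give_block_templates(self):
        m = scaled_matrix(np.zeros((6, 2)), list("abcdef"), ["u", "v"])
        t = build_templates([marker("A", ["a", "b", "c"]), marker("B", ["d", "e", "f"])], m)
        assert t.template_matrix.sum(axis=0).tolist() == [3.0, 3.0]

    def test_shared_gene_marks_both_columns(self):
        m = scaled_matrix(np.zeros((3, 2)), ["a", "b", "c"], ["u", "v"])
        t = build_templates([marker("A", ["a", "b"]), marker("B", ["b", "c"])], m)
        row_b = t.template_matrix[list(t.feature_genes).index("b")]
        assert row_b.tolist() == [1.0, 1.0]

    def test_partially_absent_set_counts_dropped_genes(self):
        m = scaled_matrix(np.zeros((2, 2)), ["a", "b"], ["u", "v"])
        t = build_templates([marker("A", ["a", "x", "y", "z", "q"]), marker("B", ["b"])], m)
        assert t.dropped_genes["A"] == 4
        assert t.genes_per_class.tolist() == [1, 1]

    def test_fully_absent_class_is_an_error(self):
        m = scaled_matrix(np.zeros((2, 2)), ["a", "b"], ["u", "v"])
        with pytest.raises(ValidationError) as err:
            build_templates([marker("A", ["a"]), marker("B", ["zz"])], m)
        assert "B" in str(err.value)


# --------------------------------------------------------------------------
# NTP
# --------------------------------------------------------------------------


class TestNTP:
    def toy(self):
        # 4 genes, 2 classes: A = {GA, GB}, B = {GC, GD}; hand-set profiles
        vals = [[2.0, -1.0, 0.3], [1.0, -0.5, 0.1], [-1.0, 2.0, -0.2], [-0.5, 1.0, 0.4]]
        m = scaled_matrix(vals, ["GA", "GB", "GC", "GD"], ["u1", "u2", "u3"])
        t = build_templates([marker("A", ["GA", "GB"]), marker("B", ["GC", "GD"])], m)
        return m, t

    def test_distances_match_bruteforce_cosine(self):
        m, t = self.toy()
        s = ntp_score(m, t, n_perm=100, seed=0)
        for j, u in enumerate(["u1", "u2", "u3"]):
            x = m.values[:, j]
            for k, cls in enumerate(["A", "B"]):
                expected = cosine_distance_oracle(x, t.template_matrix[:, k])
                assert s.scores.loc[u, cls] == pytest.approx(expected, abs=1e-12)

    def test_unit_equal_to_template_has_zero_distance(self):
        m = scaled_matrix([[1.0], [1.0], [0.0]], ["a", "b", "c"], ["u"])
        t = build_templates([marker("A", ["a", "b"]), marker("B", ["c"])], m)
        s = ntp_score(m, t, n_perm=100, seed=0)
        assert s.scores.loc["u", "A"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_unit_has_distance_half(self):
        m = scaled_matrix([[1.0], [-1.0], [0.5]], ["a", "b", "c"], ["u"])
        t = build_templates([marker("A", ["a", "b"]), marker("B", ["c"])], m)
        s = ntp_score(m, t, n_perm=100, seed=0)
        assert s.scores.loc["u", "A"] == pytest.approx(0.5, abs=1e-12)

    def test_distances_invariant_to_positive_unit_scaling(self):
        m, t = self.toy()
        doubled = ExpressionMatrix(m.values * 2.5, m.gene_ids, m.cell_ids, "scaled")
        a = ntp_score(m, t, n_perm=100, seed=0).scores
        b = ntp_score(doubled, t, n_perm=100, seed=0).scores
        pd.testing.assert_frame_equal(a, b)

    def test_gene_row_permutation_invariance(self):
        m, t = self.toy()
        perm = [2, 0, 3, 1]
        mp = ExpressionMatrix(m.values[perm], m.gene_ids[perm], m.cell_ids, "scaled")
        tp = build_templates([marker("A", ["GA", "GB"]), marker("B", ["GC", "GD"])], mp)
        a = ntp_score(m, t, n_perm=100, seed=0).scores
        b = ntp_score(mp, tp, n_perm=100, seed=0).scores
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_unit_flagged_unresolved(self):
        m = scaled_matrix([[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0]], ["a", "b", "c"], ["u", "z"])
        t = build_templates([marker("A", ["a", "b"]), marker("B", ["c"])], m)
        s = ntp_score(m, t, n_perm=100, seed=0)
        assert bool(s.unresolved.loc["z"]) and s.pvalues.loc["z"] == 1.0

    def test_null_pvalues_uniform_on_iid_noise(self):
        rng = np.random.default_rng(7)
        G, U = 600, 300
        m = scaled_matrix(rng.normal(size=(G, U)),
                          [f"g{i}" for i in range(G)], [f"c{i}" for i in range(U)])
        sets = [marker(f"t{k}", [f"g{i}" for i in rng.choice(G, 25, replace=False)])
                for k in range(3)]
        s = ntp_score(m, build_templates(sets, m), n_perm=500, seed=5)
        assert kstest(s.pvalues.to_numpy(), "uniform").pvalue > 0.01

    def test_determinism_under_seed(self):
        m, t = self.toy()
        a = ntp_score(m, t, n_perm=120, seed=3)
        b = ntp_score(m, t, n_perm=120, seed=3)
        pd.testing.assert_series_equal(a.pvalues, b.pvalues)


# --------------------------------------------------------------------------
# GSEA
# --------------------------------------------------------------------------


class TestGSEA:
    def test_all_hits_on_top_with_weight_zero_gives_es_one(self):
        vals = [[5.0], [4.0], [3.0], [0.1], [0.0], [-1.0]]
        m = scaled_matrix(vals, list("abcdef"), ["u"])
        s = gsea_score(m, [marker("A", ["a", "b", "c"]), marker("B", ["f"])], weight=0)
        assert s.scores.loc["u", "A"] == pytest.approx(1.0)

    def test_all_hits_at_bottom_gives_negative_es(self):
        vals = [[5.0], [4.0], [3.0], [-1.0], [-2.0]]
        m = scaled_matrix(vals, list("abcde"), ["u"])
        s = gsea_score(m, [marker("A", ["d", "e"]), marker("B", ["a"])], weight=0)
        assert -1.0 <= s.scores.loc["u", "A"] < 0

    def test_matches_bruteforce_enumeration(self):
        # N=10, hits at ranks {1, 2, 7} (descending metric order), weight 0
        metric = [10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        genes = [f"g{i}" for i in range(10)]
        hits = ["g0", "g1", "g6"]
        m = scaled_matrix([[v] for v in metric], genes, ["u"])
        for w in (0.0, 1.0):
            s = gsea_score(m, [marker("A", hits), marker("B", ["g9"])], weight=w)
            expected = es_oracle(metric, [g in hits for g in genes], w)
            assert s.scores.loc["u", "A"] == pytest.approx(expected, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2 ** 10 - 2))
    def test_es_bounded_and_complement_antisymmetric_at_weight_zero(self, bits):
        # every non-trivial hit pattern over 10 ranked genes
        hit = [(bits >> i) & 1 == 1 for i in range(10)]
        if not any(hit) or all(hit):
            return
        metric = [float(10 - i) for i in range(10)]
        genes = [f"g{i}" for i in range(10)]
        m = scaled_matrix([[v] for v in metric], genes, ["u"])
        set_a = [g for g, h in zip(genes, hit) if h]
        set_b = [g for g, h in zip(genes, hit) if not h]
        s = gsea_score(m, [marker("A", set_a), marker("B", set_b)], weight=0)
        es_a, es_b = s.scores.loc["u", "A"], s.scores.loc["u", "B"]
        assert -1.0 <= es_a <= 1.0 and -1.0 <= es_b <= 1.0
        # at weight 0 a set's running sum is the negative of its complement's
        assert es_a == pytest.approx(-es_b, abs=1e-9)

    def test_set_covering_all_genes_rejected(self):
        m = scaled_matrix([[1.0], [2.0]], ["a", "b"], ["u"])
        with pytest.raises(ValidationError):
            gsea_score(m, [marker("A", ["a", "b"]), marker("B", ["a"])])

    def test_gene_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 3))
        genes = [f"g{i}" for i in range(8)]
        m = scaled_matrix(vals, genes, ["u", "v", "w"])
        sets = [marker("A", ["g0", "g3"]), marker("B", ["g5", "g6"])]
        perm = rng.permutation(8)
        mp = ExpressionMatrix(vals[perm], np.array(genes, object)[perm], m.cell_ids, "scaled")
        pd.testing.assert_frame_equal(gsea_score(m, sets).scores, gsea_score(mp, sets).scores)


# --------------------------------------------------------------------------
# average score & assignment
# --------------------------------------------------------------------------


class TestAverageScore:
    def test_mean_of_marker_values(self):
        m = scaled_matrix([[1.0], [2.0], [6.0], [9.0]], ["a", "b", "c", "x"], ["u"])
        s = average_score(m, [marker("A", ["a", "b", "c"]), marker("B", ["x"])])
        assert s.scores.loc["u", "A"] == pytest.approx(3.0)

    def test_all_zero_unit_scores_zero_everywhere(self):
        m = scaled_matrix(np.zeros((3, 1)), ["a", "b", "c"], ["u"])
        s = average_score(m, [marker("A", ["a"]), marker("B", ["b", "c"])])
        assert (s.scores.loc["u"] == 0).all()

    def test_elevated_marker_class_wins(self):
        m = scaled_matrix([[2.0], [2.0], [0.0], [0.0]], ["a", "b", "c", "d"], ["u"])
        s = average_score(m, [marker("A", ["a", "b"]), marker("B", ["c", "d"])])
        assert assign_types(s).assignments.loc["u"] == "A"


class TestAssignTypes:
    def test_tied_scores_go_to_first_class(self, caplog):
        scores = pd.DataFrame([[0.5, 0.5]], index=["u"], columns=["A", "B"])
        from markertyper.typing import TypingScores
        res = assign_types(TypingScores(method="average", scores=scores))
        assert res.assignments.loc["u"] == "A"

    def test_ntp_high_fdr_is_unresolved(self):
        from markertyper.typing import TypingScores
        scores = pd.DataFrame([[0.1, 0.4]], index=["u"], columns=["A", "B"])
        s = TypingScores(method="ntp", scores=scores,
                         pvalues=pd.Series([0.2], index=["u"]),
                         fdr=pd.Series([0.2], index=["u"]),
                         unresolved=pd.Series([False], index=["u"]))
        assert assign_types(s, fdr_cutoff=0.05).assignments.loc["u"] == "Unresolved"

    def test_cluster_assignment_broadcasts_to_member_cells(self):
        import pandas as pd

        from markertyper.preprocess import CellMeta
        from markertyper.typing import TypingResult
        res = TypingResult(
            table=pd.DataFrame({"unit_id": ["k1", "k2"], "assigned_type": ["A", "B"],
                                "score": [1.0, 2.0], "p": [np.nan] * 2, "fdr": [np.nan] * 2}),
            method="average", level="cluster")
        meta = CellMeta(pd.DataFrame({"cell_id": ["c1", "c2", "c3"],
                                      "cluster": ["k1", "k2", "k1"]}))
        out = res.broadcast_to_cells(meta)
        assert out.assignments.tolist() == ["A", "B", "A"]


class TestBH:
    def test_matches_hand_computation(self):
        # q_i = min_{j>=i} p_j * m / j: (0.03, 0.03, 0.03)
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_p_passes_through(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_monotone_when_sorted(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=50))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()
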
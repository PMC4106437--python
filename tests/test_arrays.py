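import numpy as np
import pytest

from nacscan.arrays import (
    ProbeRecord,
    background_correct_half,
    de_to_frame,
    deduplicate_probes,
    filter_low_signal,
    flag_outlier_arrays,
    match_probe_to_gene,
    quantile_normalize,
    rank_differential,
    select_representative_probe,
    select_top,
)
from nacscan.simulate import SimConfig, gen_microarray


class TestBackgroundCorrect:
    def test_subtraction_and_floor(self):
        raw = np.array([[100.0, 10.0], [0.0, 5.0]])
        bg = np.array([[30.0, 50.0], [0.0, 5.0]])
        out = background_correct_half(raw, bg)
        assert out[0, 0] == 70.0
        assert out[0, 1] == 0.5
        assert np.all(out > 0)

    def test_zero_background_identity_above_floor(self):
        raw = np.array([[2.0, 0.1]])
        out = background_correct_half(raw, np.zeros_like(raw))
        assert out[0, 0] == 2.0
        assert out[0, 1] == 0.5

    def test_shape_mismatch_names_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(2, 3\)"):
            background_correct_half(np.ones((2, 2)), np.ones((2, 3)))

    def test_nonfinite_entry_located(self):
        raw = np.ones((3, 2))
        raw[1, 1] = np.inf
        with pytest.raises(ValueError, match="probe 1, array 1"):
            background_correct_half(raw, np.zeros((3, 2)))


class TestQuantileNormalize:
    def test_two_column_example(self):
        X = np.array([[1.0, 6.0], [2.0, 4.0], [3.0, 2.0]])
        out = quantile_normalize(X)
        assert np.allclose(out[:, 0], [1.5, 3.0, 4.5])
        assert np.allclose(out[:, 1], [4.5, 3.0, 1.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 7.0, 2.0])
        X = np.column_stack([col, col])
        assert np.allclose(quantile_normalize(X), X)

    def test_column_means_equal(self, rng):
        X = rng.lognormal(3, 1, size=(200, 6))
        out = quantile_normalize(X)
        means = out.mean(axis=0)
        assert np.allclose(means, means[0])

    def test_rank_order_preserved(self, rng):
        X = rng.normal(size=(50, 4))
        out = quantile_normalize(X)
        for j in range(4):
            assert np.array_equal(np.argsort(X[:, j]), np.argsort(out[:, j]))

    def test_idempotent_on_tie_free_input(self, rng):
        X = rng.normal(size=(80, 5))
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_ties_get_mean_value(self):
        X = np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0]])
        out = quantile_normalize(X)
        assert out[0, 0] == out[1, 0]

    def test_single_column_returned_unchanged(self, caplog):
        X = np.array([[1.0], [2.0]])
        with caplog.at_level("WARNING"):
            out = quantile_normalize(X)
        assert np.array_equal(out, X)
        assert "single column" in caplog.text


class TestLowSignalFilter:
    def test_trivial_keep_and_drop(self):
        X = np.array([[100.0, 100.0], [10.0, 10.0]])
        bg = np.full((2, 2), 30.0)
        kept, n = filter_low_signal(X, bg, 1.1, 1.0, probe_ids=["hi", "lo"])
        assert kept == ["hi"] and n == 1

    def test_planted_dead_probes_removed(self):
        cfg = SimConfig(n_genes=150, dead_probe_fraction=0.1, seed=3)
        arrays, probes, truth = gen_microarray(cfg)
        corrected = background_correct_half(arrays.raw, arrays.background)
        kept, _ = filter_low_signal(
            corrected,
            arrays.background,
            min_fold_over_bg=1.1,
            min_fraction_arrays=1.0,
            probe_ids=arrays.probe_ids,
            group_labels=arrays.group_labels,
        )
        dropped = set(arrays.probe_ids) - set(kept)
        assert dropped == truth["dead_probes"]

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            filter_low_signal(np.ones((2, 2)), np.ones((2, 2)), -1.0, 0.5)
        with pytest.raises(ValueError):
            filter_low_signal(np.ones((2, 2)), np.ones((2, 2)), 1.1, 0.0)


def probe(pid, mean, dist, target="t1"):
    return ProbeRecord(
        probe_id=pid,
        target_id=target,
        probe_seq="ACGT" * 15,
        dist_to_3prime=dist,
        signals=np.full(4, float(mean)),
    )


class TestRepresentativeProbe:
    def test_single_probe(self):
        assert select_representative_probe([probe("a", 5, 100)]) == "a"

    def test_top_two_then_most_3prime(self):
        probes = [probe("A", 10, 50), probe("B", 8, 10), probe("C", 2, 0)]
        assert select_representative_probe(probes) == "B"

    def test_distance_tie_higher_signal(self):
        probes = [probe("A", 10, 10), probe("B", 8, 10)]
        assert select_representative_probe(probes) == "A"

    def test_full_tie_lexicographic(self):
        probes = [probe("B", 8, 10), probe("A", 8, 10)]
        assert select_representative_probe(probes) == "A"

    def test_order_invariance(self, rng):
        probes = [probe(f"p{i}", float(rng.integers(1, 20)), int(rng.integers(0, 500)))
                  for i in range(6)]
        expected = select_representative_probe(probes)
        for _ in range(5):
            rng.shuffle(probes)
            assert select_representative_probe(probes) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_representative_probe([])

    def test_dedup_one_probe_per_gene(self):
        cfg = SimConfig(n_genes=80, seed=5)
        _, probes, _ = gen_microarray(cfg)
        rep = deduplicate_probes(probes)
        assert len(rep) == 80
        assert all(rep[t].startswith(t) for t in rep)


class TestProbeMatching:
    GENE = "TTTT" + "ACGTACGTACGTACGTACGT" + "GGGG"

    def test_exact_substring(self):
        genes = {"g1": self.GENE, "g2": "C" * 40}
        assert match_probe_to_gene("ACGTACGTACGT", genes) == "g1"

    def test_boundary_three_mismatches(self):
        probe_seq = "TTTTACGTACGT"
        window = probe_seq.replace("T", "A", 3)  # 3 mismatches to g1 window
        genes = {"g1": "CC" + probe_seq + "CC"}
        assert match_probe_to_gene(window, genes, max_mismatch=3) == "g1"
        window4 = "CCCC" + probe_seq[4:]  # 4 mismatches
        assert match_probe_to_gene(window4, genes, max_mismatch=3) is None

    def test_ambiguous_bases_count_as_mismatch(self):
        genes = {"g1": "AAAAACGTACGTAAAAA"}
        assert match_probe_to_gene("NCGTNCGT", genes, max_mismatch=1) is None
        assert match_probe_to_gene("NCGTACGT", genes, max_mismatch=1) == "g1"

    def test_smallest_distance_then_lexicographic(self):
        probe_seq = "ACGTACGTAC"
        genes = {
            "b": "TT" + probe_seq + "TT",
            "a": "TT" + probe_seq[:-1] + "G" + "TT",
        }
        assert match_probe_to_gene(probe_seq, genes) == "b"
        genes["a"] = genes["b"]
        assert match_probe_to_gene(probe_seq, genes) == "a"


class TestRankDifferential:
    def test_null_gene_has_zero_stat(self):
        X = np.array([[1.0, 1.0, 2.0, 2.0], [5.0, 5.0, 5.0, 5.0]])
        de = rank_differential(X, ["a", "a", "b", "b"], ("a", "b"),
                               gene_ids=["shift", "flat"])
        flat = next(r for r in de if r.gene_id == "flat")
        assert flat.log2fc == 0.0
        assert flat.stat == 0.0

    def test_bh_adjustment_matches_reference(self, rng):
        """BH within the ranking equals an independent implementation."""
        from statsmodels.stats.multitest import multipletests

        X = rng.normal(size=(40, 6))
        de = rank_differential(X, ["a"] * 3 + ["b"] * 3, ("a", "b"))
        de_sorted = sorted(de, key=lambda r: r.gene_id)
        p = np.array([r.p for r in de_sorted])
        p_adj = np.array([r.p_adj for r in de_sorted])
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(p_adj, expected)
        assert np.all(p_adj >= p - 1e-12)

    def test_planted_shift_recovered_at_top(self, rng):
        n_genes, n_shift = 500, 50
        X = rng.normal(8.0, 0.5, size=(n_genes, 8))
        X[:n_shift, 4:] += 4.0
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]
        de = rank_differential(X, ["ns"] * 4 + ["sen"] * 4, ("ns", "sen"),
                               gene_ids=gene_ids)
        top = {r.gene_id for r in de if r.rank <= n_shift}
        assert top == set(gene_ids[:n_shift])

    def test_null_pvalues_uniform(self):
        """Raw moderated-t p-values on null data: fraction <= 0.05 within
        99% binomial bounds of nominal."""
        rng = np.random.default_rng(99)
        n = 2000
        X = rng.normal(size=(n, 8))
        de = rank_differential(X, ["a"] * 4 + ["b"] * 4, ("a", "b"))
        frac = np.mean([r.p <= 0.05 for r in de])
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) <= half_width

    def test_single_array_group_falls_back_to_fold_change(self, caplog):
        X = np.array([[1.0, 5.0, 5.0], [1.0, 1.1, 1.2]])
        with caplog.at_level("WARNING"):
            de = rank_differential(X, ["a", "b", "b"], ("a", "b"))
        assert de[0].rank == 1 and np.isnan(de[0].p)
        assert "single array" in caplog.text

    def test_ranks_are_permutation(self, rng):
        X = rng.normal(size=(30, 6))
        de = rank_differential(X, ["a"] * 3 + ["b"] * 3, ("a", "b"))
        assert sorted(r.rank for r in de) == list(range(1, 31))


class TestSelectTop:
    def test_printed_scale_percentage(self):
        de = [
            type("R", (), {"gene_id": f"g{i}", "rank": i + 1})()
            for i in range(24646)
        ]
        chosen, percent = select_top(de, 5000)
        assert percent == 20
        assert len(chosen) == 5000

    def test_all_and_single(self):
        de = [
            type("R", (), {"gene_id": f"g{i}", "rank": i + 1})()
            for i in range(10)
        ]
        chosen, percent = select_top(de, 10)
        assert percent == 100 and len(chosen) == 10
        chosen1, _ = select_top(de, 1)
        assert chosen1 == {"g0"}

    def test_bad_count(self):
        de = [type("R", (), {"gene_id": "g", "rank": 1})()]
        with pytest.raises(ValueError):
            select_top(de, 0)
        with pytest.raises(ValueError):
            select_top(de, 2)


class TestOutlierArrays:
    def test_low_correlation_array_flagged(self, rng):
        base = rng.normal(size=(300,))
        X = np.column_stack([base + rng.normal(0, 0.1, 300) for _ in range(7)])
        X[:, 3] = rng.normal(size=300)  # unrelated array
        assert flag_outlier_arrays(X) == [3]

    def test_clean_cohort_unflagged(self, rng):
        base = rng.normal(size=(300,))
        X = np.column_stack([base + rng.normal(0, 0.1, 300) for _ in range(6)])
        assert flag_outlier_arrays(X) == []
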
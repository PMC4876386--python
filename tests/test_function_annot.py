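"""ORF calling, greedy clustering, best-hit mapping, counting and rollup."""

import numpy as np
import pandas as pd
import pytest

from metatrans._align import local_identity_coverage
from metatrans.function_annot import (
    CatalogEntry,
    CatalogIndex,
    aggregate_counts,
    cluster_greedy,
    map_best_hit,
    predict_fragments,
    rollup,
)
from metatrans.seqio import AbundanceMatrix, SeqRecord, revcomp

from conftest import make_read, mutate_at, random_seq
from _oracles import greedy_cluster_brute, smith_waterman

NONSTOP = "GCA"  # alanine codon; no stop in any window of repeats


def stop_free(n_codons: int, rng) -> str:
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    return "".join(codons[int(i)] for i in rng.integers(0, len(codons), size=n_codons))


class TestPredictFragments:
    def test_stop_free_read_yields_full_frame(self, rng):
        seq = stop_free(22, rng)  # 66 nt, no stop in frame +0
        frags = predict_fragments(SeqRecord("r", seq))
        plus0 = [f for f in frags if f.strand == "+" and f.frame == 0]
        assert len(plus0) == 1
        assert (plus0[0].start, plus0[0].end) == (0, 66)
        assert plus0[0].nt_seq == seq

    def test_short_read_discarded(self):
        assert predict_fragments(SeqRecord("r", "ACG" * 10)) == []

    def test_dense_stop_lattice_discards_read(self):
        # stops planted in all six frames every <= 9 codons leave no run >= 60 nt
        block = bytearray(b"G" * 27)
        for off in (0, 10, 20):
            block[off : off + 3] = b"TAA"  # forward-strand stops, frames 0/1/2
        for off in (4, 14, 24):
            block[off : off + 3] = b"TTA"  # reverse-strand stops
        seq = (bytes(block) * 4).decode()
        assert predict_fragments(SeqRecord("r", seq)) == []

    def test_coordinates_map_back_to_read(self, rng):
        seq = random_seq(rng, 200)
        for frag in predict_fragments(SeqRecord("r", seq)):
            assert (frag.end - frag.start) % 3 == 0
            sub = seq[frag.start : frag.end]
            assert frag.nt_seq == (sub if frag.strand == "+" else revcomp(sub))

    def test_tags_inherited(self, rng):
        seq = stop_free(30, rng)
        frags = predict_fragments(SeqRecord("r", seq, None, {"copies": 7}))
        assert all(f.copies == 7 for f in frags)


class TestClusterGreedy:
    def test_identical_fragments_share_cluster(self, rng):
        seq = random_seq(rng, 100)
        items = [make_read("a", seq), make_read("b", seq)]
        clusters = cluster_greedy(items)
        assert len(clusters) == 1
        assert clusters[0].weight == 2
        assert clusters[0].rep.csize == 2

    @pytest.mark.parametrize("n_mismatch, together", [(4, True), (6, False)])
    def test_identity_threshold_at_95(self, rng, n_mismatch, together):
        seq = random_seq(rng, 100)
        positions = np.linspace(10, 85, n_mismatch).astype(int)
        other = mutate_at(seq, positions)
        clusters = cluster_greedy([make_read("a", seq), make_read("b", other)])
        assert (len(clusters) == 1) is together

    def test_partial_coverage_founds_new_cluster(self, rng):
        rep = random_seq(rng, 100)
        partial = rep[:60] + random_seq(rng, 40)  # only 60% of its length matches
        clusters = cluster_greedy([make_read("a", rep), make_read("b", partial)])
        assert len(clusters) == 2

    def test_weight_conservation_and_partition(self, rng):
        items = []
        base = random_seq(rng, 90)
        for i in range(40):
            seq = mutate_at(base, rng.integers(0, 90, size=int(rng.integers(0, 8))))
            items.append(make_read(f"r{i}", seq, tags={"copies": int(rng.integers(1, 5))}))
        clusters = cluster_greedy(items)
        assert sum(c.weight for c in clusters) == sum(r.copies for r in items)
        all_members = [m for c in clusters for m in c.member_ids]
        assert sorted(all_members) == sorted(r.id for r in items)

    def test_members_mode_counts_cardinality(self, rng):
        seq = random_seq(rng, 80)
        items = [make_read("a", seq, tags={"copies": 5}), make_read("b", seq)]
        clusters = cluster_greedy(items, csize_mode="members")
        assert clusters[0].weight == 2

    def test_matches_all_pairs_oracle(self, rng):
        items = _mixed_fragment_set(rng, n=60)
        clusters = cluster_greedy(items)

        def predicate(q, r):
            if q in r:
                return 100.0, 1.0
            identity, coverage, _ = local_identity_coverage(q, r)
            return identity, coverage

        expected = greedy_cluster_brute(items, predicate)
        assert [c.member_ids for c in clusters] == expected


def _mixed_fragment_set(rng, n):
    items = []
    families = [random_seq(rng, int(rng.integers(60, 140))) for _ in range(6)]
    for i in range(n):
        fam = families[int(rng.integers(0, len(families)))]
        if rng.random() < 0.3:
            seq = random_seq(rng, int(rng.integers(60, 140)))
        else:
            seq = mutate_at(fam, rng.integers(0, len(fam), size=int(rng.integers(0, 6))))
            if rng.random() < 0.3:  # truncate to stress the coverage rule
                cut = int(rng.integers(len(fam) // 2, len(fam)))
                seq = seq[:cut]
        items.append(make_read(f"r{i}", seq))
    return items


class TestMapBestHit:
    @pytest.fixture
    def catalog(self, rng):
        genes = [CatalogEntry(f"G{i:02d}", random_seq(rng, 400)) for i in range(10)]
        return CatalogIndex(genes), genes

    def test_exact_substring_is_perfect_hit(self, catalog):
        index, genes = catalog
        query = make_read("q", genes[3].seq[100:176])
        hit = map_best_hit(query, index)
        assert hit is not None
        assert (hit.gene_id, hit.identity, hit.coverage) == ("G03", 100.0, 1.0)

    def test_reverse_strand_query_maps(self, catalog):
        index, genes = catalog
        query = make_read("q", revcomp(genes[5].seq[50:130]))
        hit = map_best_hit(query, index)
        assert hit is not None and hit.gene_id == "G05"

    def test_tie_broken_lexicographically(self, rng):
        seq = random_seq(rng, 300)
        index = CatalogIndex([CatalogEntry("B", seq), CatalogEntry("A", seq)])
        hit = map_best_hit(make_read("q", seq[40:120]), index)
        assert hit is not None and hit.gene_id == "A"

    def test_divergent_query_unmapped(self, catalog, rng):
        index, genes = catalog
        mutated = mutate_at(
            genes[0].seq[100:176], rng.choice(76, size=23, replace=False)
        )  # ~70% identity
        assert map_best_hit(make_read("q", mutated), index) is None

    def test_empty_catalog_is_config_error(self):
        with pytest.raises(ValueError, match="empty catalog"):
            CatalogIndex([])

    def test_hit_values_match_alignment_oracle(self, catalog, rng):
        index, genes = catalog
        for _ in range(40):
            gene = genes[int(rng.integers(0, len(genes)))]
            start = int(rng.integers(0, len(gene.seq) - 76))
            query_seq = gene.seq[start : start + 76]
            n_mut = int(rng.integers(0, 6))
            query_seq = mutate_at(query_seq, rng.choice(76, size=n_mut, replace=False))
            hit = map_best_hit(make_read("q", query_seq), index)
            if hit is None:
                continue
            target = next(g.seq for g in genes if g.gene_id == hit.gene_id)
            score, identity, coverage, cols = smith_waterman(query_seq, target)
            assert hit.identity == pytest.approx(identity, abs=2.0)
            assert hit.coverage == pytest.approx(coverage, abs=0.05)


class TestCounting:
    def test_weights_multiply_copies_and_csize(self):
        hit = [type("H", (), {"query_id": "q1", "gene_id": "G1"})()]
        # use the real Hit class for fidelity
        from metatrans.function_annot import Hit

        hits = {"s1": [Hit("q1", "G1", 100.0, 1.0)]}
        queries = {"s1": [SeqRecord("q1", "ACGT", None, {"copies": 3, "csize": 2})]}
        matrix = aggregate_counts(hits, queries)
        assert matrix.df.loc["G1", "s1"] == 6

    def test_sum_over_queries(self):
        from metatrans.function_annot import Hit

        hits = {"s": [Hit("q1", "G1", 100.0, 1.0), Hit("q2", "G1", 99.0, 1.0)]}
        queries = {
            "s": [
                SeqRecord("q1", "ACGT"),
                SeqRecord("q2", "ACGT", None, {"copies": 4}),
            ]
        }
        assert aggregate_counts(hits, queries).df.loc["G1", "s"] == 5

    def test_duplicate_query_hits_discarded_with_warning(self):
        from metatrans.function_annot import Hit

        hits = {"s": [Hit("q1", "G1", 100.0, 1.0), Hit("q1", "G2", 98.0, 1.0)]}
        queries = {"s": [SeqRecord("q1", "ACGT")]}
        with pytest.warns(UserWarning, match="duplicate hit"):
            matrix = aggregate_counts(hits, queries)
        assert matrix.df.loc["G1", "s"] == 1
        assert "G2" not in matrix.features

    def test_no_hits_gives_empty_matrix(self):
        matrix = aggregate_counts({"s": []}, {"s": []})
        assert matrix.shape[0] == 0 and matrix.samples == ["s"]


class TestRollup:
    @pytest.fixture
    def annotations(self):
        return pd.DataFrame(
            {
                "og_id": ["OG1", "OG1", "OG2", "OG3", ""],
                "ko_id": ["K1", "K1", "K2", "K3", ""],
                "category": ["E", "E", "E", "C", ""],
            },
            index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
        )

    def test_two_level_sums(self, annotations):
        matrix = AbundanceMatrix.from_dict(
            {"g1": {"s": 2}, "g2": {"s": 3}, "g3": {"s": 1}, "g4": {"s": 4}},
            samples=["s"],
        )
        og, cat = rollup(matrix, annotations.drop("g5"))
        assert og.df.loc["OG1", "s"] == 5
        assert cat.df.loc["E", "s"] == 6  # OG1 (5) + OG2 (1)
        assert cat.df.loc["C", "s"] == 4
        assert og.df.to_numpy().sum() == matrix.df.to_numpy().sum()

    def test_unannotated_genes_sink_to_unknown(self, annotations):
        matrix = AbundanceMatrix.from_dict(
            {"g5": {"s": 7}, "novel": {"s": 2}}, samples=["s"]
        )
        with pytest.warns(UserWarning, match="absent"):
            og, cat = rollup(matrix, annotations)
        assert og.df.loc["unknown", "s"] == 9
        assert cat.df.loc["unknown", "s"] == 9
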
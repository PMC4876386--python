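"""Mock-community construction, read simulation, decontamination, ROC scoring."""

import numpy as np
import pandas as pd
import pytest

from metatrans.function_annot import CatalogEntry
from metatrans.seqio import MAX_PHRED, SeqRecord, read_fastq
from metatrans.simulate_eval import (
    DOWN,
    NULL,
    UP,
    QualityModel,
    assign_de,
    build_mock,
    decontaminate_reference,
    roc_auc,
    score_genes,
    simulate_counts,
    simulate_reads,
    synthesize_16s_references,
    synthesize_coding_genes,
    synthesize_source_genomes,
    train_quality_model,
)

from conftest import make_read, mutate_at, random_seq
from _oracles import auc_concordance


class TestBuildMock:
    def test_exact_draw_per_organism(self):
        pools = synthesize_source_genomes(5, 1200, seed=0)
        genes = build_mock(pools, genes_per_org=1000, seed=1)
        assert len(genes) == 5000
        assert len({g.id for g in genes}) == 5000  # without replacement

    def test_too_small_pool_names_organism(self):
        pools = synthesize_source_genomes(2, 999, seed=0)
        with pytest.raises(ValueError, match="org1"):
            build_mock(pools, genes_per_org=1000)

    def test_deterministic_given_seed(self):
        pools = synthesize_source_genomes(2, 50, seed=0)
        a = build_mock(pools, genes_per_org=20, seed=7)
        b = build_mock(pools, genes_per_org=20, seed=7)
        assert [g.id for g in a] == [g.id for g in b]


class TestAssignDe:
    @pytest.mark.parametrize("n_genes, n_up", [(1000, 200), (10, 2)])
    def test_label_bookkeeping(self, rng, n_genes, n_up):
        genes = synthesize_coding_genes(n_genes, rng)
        design = assign_de(genes, seed=3)
        labels = pd.Series(design.labels)
        assert (labels == UP).sum() == n_up
        assert (labels == DOWN).sum() == n_up
        assert (labels == NULL).sum() == n_genes - 2 * n_up
        assert set(design.fold_change.values()) <= {4.0, 0.25, 1.0}

    def test_zero_fractions_all_null(self, rng):
        genes = synthesize_coding_genes(10, rng)
        design = assign_de(genes, frac_up=0.0, frac_down=0.0)
        assert all(lab == NULL for lab in design.labels.values())

    def test_overfull_design_rejected(self, rng):
        genes = synthesize_coding_genes(10, rng)
        with pytest.raises(ValueError):
            assign_de(genes, frac_up=0.6, frac_down=0.6)


class TestSimulateCounts:
    def test_fold_change_recovered_in_group_means(self, rng):
        genes = synthesize_coding_genes(60, rng)
        design = assign_de(genes, seed=5, n1=50, n2=50, mean_per_kb=40.0)
        counts = simulate_counts(design, seed=6).df
        g1, g2 = design.samples
        m1 = counts[g1].mean(axis=1)
        m2 = counts[g2].mean(axis=1)
        for gene, label in design.labels.items():
            expected = design.fold_change[gene]
            mu = m1.loc[gene]
            # 3 sigma of the ratio estimate under NB sampling
            phi = design.dispersion
            sd = np.sqrt((mu + phi * mu**2) / 50)
            ratio = m2.loc[gene] / m1.loc[gene]
            tol = 3 * sd / mu * (expected + 1)
            assert abs(ratio - expected) < max(tol, 0.75)

    def test_zero_dispersion_is_poisson(self, rng):
        genes = synthesize_coding_genes(1, rng, min_len=900, max_len=900)
        design = assign_de(genes, frac_up=0, frac_down=0, n1=400, n2=400,
                           mean_per_kb=20.0, dispersion=0.0)
        counts = simulate_counts(design, seed=1).df.to_numpy().ravel()
        ratio = counts.var() / counts.mean()
        assert 0.8 < ratio < 1.2


class TestSimulateReads:
    @pytest.fixture
    def small_sim(self, rng, tmp_path):
        genes = synthesize_coding_genes(8, rng, min_len=300, max_len=600)
        design = assign_de(genes, seed=2, n1=1, n2=1, mean_per_kb=30.0)
        counts = simulate_counts(design, seed=3)
        qm = QualityModel.flat(40)
        paths = simulate_reads(design, counts, qm, tmp_path / "reads", seed=4)
        return design, counts, paths

    def test_read_counts_match_truth(self, small_sim):
        design, counts, paths = small_sim
        for sample, (p1, p2) in paths.items():
            reads1 = list(read_fastq(p1))
            reads2 = list(read_fastq(p2))
            assert len(reads1) == len(reads2) == counts.df[sample].sum()
            per_gene = pd.Series([r.id.rsplit(".", 1)[0] for r in reads1]).value_counts()
            for gene, c in counts.df[sample].items():
                assert per_gene.get(gene, 0) == c

    def test_read_length_and_quality_ranges(self, small_sim):
        _, _, paths = small_sim
        p1, _ = next(iter(paths.values()))
        for rec in read_fastq(p1):
            assert len(rec.seq) == 76
            assert all(0 <= q <= MAX_PHRED for q in rec.qual)

    def test_flat_q40_error_rate(self, rng, tmp_path):
        # one long gene, enough reads for >= 1e6 bases
        genes = [SeqRecord("g1", random_seq(rng, 1400))]
        design = assign_de(genes, frac_up=0, frac_down=0, seed=1, n1=1, n2=1,
                           mean_per_kb=10_000.0)
        counts = simulate_counts(design, seed=2)
        paths = simulate_reads(design, counts, QualityModel.flat(40), tmp_path, seed=3)
        gene = genes[0].seq
        errors = bases = 0
        p1, _ = next(iter(paths.values()))
        for rec in read_fastq(p1):
            if gene.find(rec.seq) < 0:  # errored read: locate best placement
                best = min(
                    sum(a != b for a, b in zip(rec.seq, gene[s : s + 76]))
                    for s in range(len(gene) - 75)
                )
                errors += best
            bases += 76
            if bases >= 1_000_000:
                break
        assert bases >= 1_000_000
        rate = errors / bases
        sigma = np.sqrt(1e-4 / bases)
        assert abs(rate - 1e-4) < 4 * sigma


class TestQualityModel:
    def test_flat_model_emits_only_that_score(self, rng):
        qm = QualityModel.flat(30, read_len=10)
        sample = qm.sample(rng, 50)
        assert (sample == 30).all()

    def test_training_reproduces_position_means(self, rng, tmp_path):
        reads = []
        for i in range(400):
            qual = [40] + [25] * 74 + [20]
            reads.append(make_read(f"r{i}", random_seq(rng, 76), qual))
        path = tmp_path / "train.fastq"
        from metatrans.seqio import write_fastq

        write_fastq(reads, path)
        qm = train_quality_model(path)
        means = qm.mean_by_position()
        assert means[0] == pytest.approx(40.0)
        assert means[-1] == pytest.approx(20.0)
        drawn = qm.sample(rng, 2000)
        assert np.all(np.abs(drawn.mean(axis=0) - means) < 0.5)

    def test_mixed_lengths_rejected(self, tmp_path, rng):
        from metatrans.seqio import write_fastq

        path = tmp_path / "mixed.fastq"
        write_fastq([make_read("a", random_seq(rng, 50)), make_read("b", random_seq(rng, 60))], path)
        with pytest.raises(ValueError, match="mixed read lengths"):
            train_quality_model(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            train_quality_model(path)


class TestDecontaminate:
    def test_identical_entry_removed_and_idempotent(self, rng):
        source = SeqRecord("src", random_seq(rng, 500))
        catalog = [
            CatalogEntry("dup", source.seq),
            CatalogEntry("other", random_seq(rng, 500)),
        ]
        kept, removed = decontaminate_reference(catalog, [source])
        assert removed == 1
        assert [e.gene_id for e in kept] == ["other"]
        kept2, removed2 = decontaminate_reference(kept, [source])
        assert removed2 == 0 and len(kept2) == len(kept)

    def test_moderate_similarity_retained(self, rng):
        source = SeqRecord("src", random_seq(rng, 500))
        mutated = mutate_at(source.seq, rng.choice(500, size=75, replace=False))  # ~85%
        kept, removed = decontaminate_reference([CatalogEntry("m", mutated)], [source])
        assert removed == 0

    def test_disjoint_catalog_unchanged(self, rng):
        catalog = [CatalogEntry(f"g{i}", random_seq(rng, 300)) for i in range(5)]
        kept, removed = decontaminate_reference(catalog, [SeqRecord("s", random_seq(rng, 400))])
        assert removed == 0 and len(kept) == 5


class TestScoring:
    def test_score_is_one_minus_nominal_p(self):
        de = pd.DataFrame({"feature": ["a", "b", "c"], "p": [0.0, 1.0, 0.25],
                           "log2fc": [2.0, -2.0, 0.1], "q": [0.0, 1.0, 0.5]})
        scored = score_genes(de)
        assert list(scored["score"]) == [1.0, 0.0, 0.75]

    def test_direction_ignored(self):
        de = pd.DataFrame({"feature": ["up", "down"], "p": [0.03, 0.03],
                           "log2fc": [2.0, -2.0], "q": [0.1, 0.1]})
        scored = score_genes(de)
        assert scored["score"].iloc[0] == scored["score"].iloc[1]


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert roc.auc == pytest.approx(1.0)

    def test_three_of_four_concordant_pairs(self):
        roc = roc_auc([0.9, 0.6, 0.8, 0.1], [True, True, False, False])
        assert roc.auc == pytest.approx(0.75)

    def test_null_scores_near_half(self, rng):
        scores = rng.random(1000)
        truth = rng.random(1000) < 0.4
        roc = roc_auc(scores, truth)
        assert abs(roc.auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc([0.1, 0.2], [True, True])

    def test_equals_pairwise_concordance_with_ties(self, rng):
        scores = rng.integers(0, 20, size=200) / 20.0  # heavy ties
        truth = rng.random(200) < 0.3
        roc = roc_auc(scores, truth)
        assert roc.auc == pytest.approx(auc_concordance(scores, truth))


class TestSynthetic16S:
    def test_unique_species_and_valid_lineages(self):
        refs = synthesize_16s_references(40, seed=1)
        assert len(refs) == 40
        species = [lin.ranks[6] for _, lin in refs]
        assert len(set(species)) == 40
        for _, lin in refs:
            assert lin.ranks[0] == "k__Bacteria"

    def test_relatives_share_higher_ranks(self):
        refs = synthesize_16s_references(30, seed=2)
        phyla = {lin.ranks[1] for _, lin in refs}
        assert 1 < len(phyla) < 30  # a real hierarchy, not star or chain

    def test_sequences_diverge_between_species(self, rng):
        refs = synthesize_16s_references(12, seed=3)
        seqs = [rec.seq for rec, _ in refs]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                diff = sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
                assert diff / len(seqs[i]) > 0.02
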
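import numpy as np
import pytest

from crpevol.collinearity import (
    CollinearBlock,
    DuplicationClass,
    HomologPair,
    chain_anchors,
    classify_duplicates,
    duplication_census,
)
from crpevol.genome_io import GeneModel

from oracles import extract_blocks_oracle


def two_chrom_annotation(n_ranks=40):
    genes = []
    for chrom in ("cA", "cB"):
        for r in range(1, n_ranks + 1):
            genes.append(
                GeneModel(f"{chrom}_{r:02d}", chrom, r * 1000, r * 1000 + 500, "+", r)
            )
    return genes


def anchors_to_pairs(positions):
    """(rank_A, rank_B) grid positions -> HomologPair list on cA x cB."""
    return [
        HomologPair(f"cA_{ra:02d}", f"cB_{rb:02d}", 100.0, 1e-20)
        for ra, rb in positions
    ]


class TestChainAnchors:
    def test_perfect_diagonal_forms_one_parallel_block(self):
        ann = two_chrom_annotation()
        pairs = anchors_to_pairs([(i, i) for i in range(1, 7)])
        blocks = chain_anchors(pairs, ann, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "parallel"
        assert blocks[0].score == 6

    def test_four_anchors_below_min_gives_no_block(self):
        ann = two_chrom_annotation()
        pairs = anchors_to_pairs([(i, i) for i in range(1, 5)])
        assert chain_anchors(pairs, ann, min_anchors=5) == []

    def test_antidiagonal_forms_antiparallel_block(self):
        ann = two_chrom_annotation()
        pairs = anchors_to_pairs([(i, 10 - i) for i in range(1, 7)])
        blocks = chain_anchors(pairs, ann, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "antiparallel"

    def test_rank_gap_limit_breaks_chain(self):
        ann = two_chrom_annotation()
        # 3 + 3 anchors separated by a 30-rank jump: no single 6-chain at gap 25
        positions = [(1, 1), (2, 2), (3, 3), (33, 33), (34, 34), (35, 35)]
        pairs = anchors_to_pairs(positions)
        assert chain_anchors(pairs, ann, max_gap_ranks=25, min_anchors=5) == []
        assert len(chain_anchors(pairs, ann, max_gap_ranks=30, min_anchors=5)) == 1

    def test_unknown_gene_in_pair_is_named(self):
        ann = two_chrom_annotation()
        with pytest.raises(KeyError, match="ghost"):
            chain_anchors([HomologPair("cA_01", "ghost")], ann)

    def test_blocks_never_share_anchors_and_use_input_pairs(self, synthetic_genome, homolog_pairs):
        genes, _, _ = synthetic_genome
        blocks = chain_anchors(homolog_pairs, genes)
        seen = set()
        pair_set = {p.genes for p in homolog_pairs}
        for b in blocks:
            for a in b.anchors:
                assert a.genes in pair_set
                assert a.genes not in seen
                seen.add(a.genes)

    def test_exhaustive_enumeration_oracle_agreement(self):
        """Greedy extraction matches brute-force max-weight chains on <=12 anchors."""
        rng = np.random.default_rng(99)
        ann = two_chrom_annotation()
        for _ in range(40):
            n = int(rng.integers(5, 13))
            cells = rng.choice(40 * 40, size=n, replace=False)
            positions = [(int(c) // 40 + 1, int(c) % 40 + 1) for c in cells]
            pairs = anchors_to_pairs(positions)
            blocks = chain_anchors(pairs, ann, max_gap_ranks=25, min_anchors=3)
            got = [
                (sorted((a.genes for a in b.anchors)), b.orientation) for b in blocks
            ]
            oracle = extract_blocks_oracle(positions, max_gap=25, min_anchors=3)
            want = [
                (sorted(anchors_to_pairs(chain)[i].genes for i in range(len(chain))), ori)
                for chain, ori in oracle
            ]
            assert got == want

    def test_lowering_min_anchors_never_loses_wgd_genes(self):
        rng = np.random.default_rng(5)
        ann = two_chrom_annotation()
        cells = rng.choice(40 * 40, size=25, replace=False)
        positions = [(int(c) // 40 + 1, int(c) % 40 + 1) for c in cells]
        pairs = anchors_to_pairs(positions)
        family = [g.gene_id for g in ann]
        previous = None
        for min_anchors in (8, 6, 4, 2):
            blocks = chain_anchors(pairs, ann, min_anchors=min_anchors)
            classes = classify_duplicates(family, pairs, blocks, ann)
            n_wgd = sum(1 for c in classes.values() if c is DuplicationClass.WGD_SEGMENTAL)
            if previous is not None:
                assert n_wgd >= previous
            previous = n_wgd


class TestClassifyDuplicates:
    def test_adjacent_rank_homologs_are_tandem(self):
        ann = two_chrom_annotation()
        pairs = [HomologPair("cA_07", "cA_08")]
        classes = classify_duplicates(["cA_07", "cA_08"], pairs, [], ann)
        assert classes["cA_07"] is DuplicationClass.TANDEM
        assert classes["cA_08"] is DuplicationClass.TANDEM

    def test_nearby_rank_homologs_are_proximal(self):
        ann = two_chrom_annotation()
        pairs = [HomologPair("cA_07", "cA_12")]
        classes = classify_duplicates(["cA_07", "cA_12"], pairs, [], ann)
        assert classes["cA_07"] is DuplicationClass.PROXIMAL

    def test_beyond_window_is_dispersed_and_no_homolog_singleton(self):
        ann = two_chrom_annotation()
        pairs = [HomologPair("cA_01", "cA_30")]
        classes = classify_duplicates(["cA_01", "cA_30", "cB_01"], pairs, [], ann)
        assert classes["cA_01"] is DuplicationClass.DISPERSED
        assert classes["cB_01"] is DuplicationClass.SINGLETON

    def test_block_anchor_outranks_tandem(self):
        ann = two_chrom_annotation()
        tandem_pair = HomologPair("cA_07", "cA_08")
        anchor = HomologPair("cA_07", "cB_07")
        block = CollinearBlock((anchor,), ("cA", "cB"), "parallel")
        classes = classify_duplicates(
            ["cA_07", "cA_08"], [tandem_pair, anchor], [block], ann
        )
        assert classes["cA_07"] is DuplicationClass.WGD_SEGMENTAL
        assert classes["cA_08"] is DuplicationClass.TANDEM

    def test_classification_is_total(self, synthetic_genome, homolog_pairs):
        genes, _, _ = synthetic_genome
        family = [g.gene_id for g in genes]
        blocks = chain_anchors(homolog_pairs, genes)
        classes = classify_duplicates(family, homolog_pairs, blocks, genes)
        assert len(classes) == len(family)

    def test_planted_structures_classified_exactly(self, synthetic_genome, homolog_pairs):
        genes, _, truth = synthetic_genome
        family = [g.gene_id for g in genes]
        blocks = chain_anchors(homolog_pairs, genes)
        classes = classify_duplicates(family, homolog_pairs, blocks, genes)
        wgd_truth = {
            g for seg in truth.planted_collinear_segments for a, b in seg for g in (a, b)
        }
        tandem_truth = {g for arr in truth.planted_tandem_arrays for g in arr}
        for g in wgd_truth:
            assert classes[g] is DuplicationClass.WGD_SEGMENTAL
        for g in tandem_truth:
            assert classes[g] is DuplicationClass.TANDEM
        for g in set(family) - wgd_truth - tandem_truth:
            assert classes[g] is DuplicationClass.SINGLETON


class TestDuplicationCensus:
    def test_all_singletons_is_hundred_percent(self):
        mapping = {f"g{i}": DuplicationClass.SINGLETON for i in range(10)}
        census = duplication_census(mapping)
        assert census["singleton"] == {"count": 10, "percent": 100.0}

    def test_counts_sum_to_family_size(self, synthetic_genome, homolog_pairs):
        genes, _, truth = synthetic_genome
        family = [g.gene_id for g in genes]
        blocks = chain_anchors(homolog_pairs, genes)
        classes = classify_duplicates(family, homolog_pairs, blocks, genes)
        census = duplication_census(classes)
        assert sum(v["count"] for v in census.values()) == len(family)
        n_anchor_genes = 2 * sum(
            len(seg) for seg in truth.planted_collinear_segments
        )
        assert census["wgd_segmental"]["count"] == n_anchor_genes

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            duplication_census({})


def test_homolog_pair_is_canonical_and_rejects_self():
    assert HomologPair("z", "a").genes == ("a", "z")
    with pytest.raises(ValueError):
        HomologPair("a", "a")
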
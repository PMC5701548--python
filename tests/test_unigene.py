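"""Spliced mapping, gene assignment, consensus exons and isoform chains."""

import itertools
import random

import pytest

from transcurate.seqio import Contig, SplicedAlignment, revcomp
from transcurate.unigene import (ConsensusGene, GeneModel, assign_to_genes,
                                 build_consensus, chains_conflict,
                                 enumerate_isoforms, read_gene_models,
                                 select_unigenes, splice_map,
                                 summarize_isoform_counts, write_gene_models)


def rand_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def toy_locus():
    """A genome with one 3-exon gene and flanking intergenic sequence."""
    rng = random.Random(100)
    parts, exons, pos = [], [], 0
    spacer = rand_nt(rng, 300)
    parts.append(spacer)
    pos += 300
    for i in range(3):
        if i:
            intron = rand_nt(rng, 120)
            parts.append(intron)
            pos += 120
        exon = rand_nt(rng, 150)
        parts.append(exon)
        exons.append((pos, pos + 150))
        pos += 150
    parts.append(rand_nt(rng, 300))
    genome = {"chr1": "".join(parts)}
    model = GeneModel("gA", "chr1", "+", exons)
    return genome, model


def transcript(genome, model, chain):
    return "".join(genome["chr1"][model.exons[i][0]:model.exons[i][1]]
                   for i in chain)


class TestSpliceMap:
    def test_two_exon_contig_maps_to_exon_coordinates(self, toy_locus):
        genome, model = toy_locus
        contig = Contig("t12", transcript(genome, model, (0, 1)))
        aln = splice_map(contig, genome)
        assert aln.strand == "+"
        assert [(b[0], b[1]) for b in aln.blocks] == model.exons[:2]
        assert aln.total_identity == 100.0

    def test_reverse_complement_maps_to_same_blocks(self, toy_locus):
        genome, model = toy_locus
        contig = Contig("t12rc", revcomp(transcript(genome, model, (0, 1))))
        aln = splice_map(contig, genome)
        assert aln.strand == "-"
        assert [(b[0], b[1]) for b in aln.blocks] == model.exons[:2]

    def test_exon_skipping_contig(self, toy_locus):
        genome, model = toy_locus
        contig = Contig("t13", transcript(genome, model, (0, 2)))
        aln = splice_map(contig, genome)
        assert [(b[0], b[1]) for b in aln.blocks] == [model.exons[0],
                                                     model.exons[2]]

    def test_unrelated_contig_unmapped(self, toy_locus):
        genome, _ = toy_locus
        rng = random.Random(999)
        assert splice_map(Contig("x", rand_nt(rng, 300)), genome) is None


def _aln(cid, blocks, target="chr1"):
    return SplicedAlignment(cid, target, "+", blocks)


class TestAssign:
    MODELS = [GeneModel("gA", "chr1", "+", [(0, 100), (200, 300)]),
              GeneModel("gB", "chr1", "+", [(500, 600), (700, 800)])]

    def test_argmax_gene(self):
        aln = _aln("c1", [(0, 100, 0, 100, 100.0), (500, 550, 100, 150, 100.0)])
        assigned, unplaced = assign_to_genes([aln], self.MODELS)
        assert assigned == {"gA": ["c1"]} and unplaced == []

    def test_disjoint_fragments_join_same_gene(self):
        a = _aln("left", [(0, 100, 0, 100, 100.0)])
        b = _aln("right", [(200, 300, 0, 100, 100.0)])
        assigned, _ = assign_to_genes([a, b], self.MODELS)
        assert assigned == {"gA": ["left", "right"]}

    def test_intergenic_alignment_unplaced(self):
        aln = _aln("c1", [(120, 180, 0, 60, 100.0)])
        assigned, unplaced = assign_to_genes([aln], self.MODELS)
        assert assigned == {} and unplaced == ["c1"]

    def test_exact_tie_takes_smaller_gene_id(self):
        aln = _aln("c1", [(0, 50, 0, 50, 100.0), (500, 550, 50, 100, 100.0)])
        assigned, _ = assign_to_genes([aln], self.MODELS)
        assert assigned == {"gA": ["c1"]}

    def test_identity_weighting(self):
        # 100 bases at 60% identity (60 weighted) lose to 80 at 100% (80)
        aln = _aln("c1", [(0, 100, 0, 100, 60.0), (500, 580, 100, 180, 100.0)])
        assigned, _ = assign_to_genes([aln], self.MODELS)
        assert assigned == {"gB": ["c1"]}

    def test_contig_order_invariance(self):
        alns = [_aln("c1", [(0, 100, 0, 100, 100.0)]),
                _aln("c2", [(200, 300, 0, 100, 100.0)]),
                _aln("c3", [(500, 600, 0, 100, 100.0)])]
        a1, _ = assign_to_genes(alns, self.MODELS)
        a2, _ = assign_to_genes(alns[::-1], self.MODELS)
        assert {g: sorted(c) for g, c in a1.items()} == \
               {g: sorted(c) for g, c in a2.items()}

    def test_overlapping_models_rejected(self):
        bad = [GeneModel("g1", "chr1", "+", [(0, 100)]),
               GeneModel("g2", "chr1", "+", [(50, 150)])]
        with pytest.raises(ValueError, match="overlap"):
            assign_to_genes([], bad)


class TestConsensus:
    MODEL = GeneModel("gA", "chr1", "+", [(0, 100), (200, 300), (400, 500)])

    def test_blocks_identical_to_model(self):
        aln = _aln("c1", [(0, 100, 0, 100, 100.0), (200, 300, 100, 200, 100.0)])
        gene = build_consensus("gA", [aln], self.MODEL, tol=6)
        assert gene.consensus_exons == self.MODEL.exons
        assert gene.assigned["c1"] == (0, 1)

    def test_block_extends_exon(self):
        aln = _aln("c1", [(200, 350, 0, 150, 100.0)])
        gene = build_consensus("gA", [aln], self.MODEL, tol=6)
        assert gene.consensus_exons[1] == (200, 350)

    def test_boundary_snapping_within_tolerance(self):
        aln = _aln("c1", [(3, 97, 0, 94, 100.0)])
        gene = build_consensus("gA", [aln], self.MODEL, tol=6)
        assert gene.consensus_exons[0] == (0, 100)

    def test_no_snapping_at_tol_zero(self):
        aln = _aln("c1", [(3, 97, 0, 94, 100.0)])
        gene = build_consensus("gA", [aln], self.MODEL, tol=0)
        assert gene.consensus_exons[0] == (0, 100)  # union still absorbs it
        aln2 = _aln("c2", [(400, 503, 0, 103, 100.0)])
        gene2 = build_consensus("gA", [aln2], self.MODEL, tol=0)
        assert gene2.consensus_exons[-1] == (400, 503)


def conflict_bruteforce(a, b):
    """Oracle: walk every exon index in the shared span."""
    if not a or not b:
        return False
    lo, hi = max(a[0], b[0]), min(a[-1], b[-1])
    for e in range(lo, hi + 1):
        if (e in a) != (e in b):
            return True
    return False


def _gene_with_chains(chains):
    gene = ConsensusGene("g", "chr1", "+",
                         [(i * 100, i * 100 + 50) for i in range(10)])
    for i, chain in enumerate(chains):
        gene.assigned[f"c{i}"] = tuple(chain)
    return gene


class TestIsoformChains:
    def test_exon_skip_conflicts(self):
        groups = enumerate_isoforms(_gene_with_chains([(1, 2, 3), (1, 3)]))
        assert len(groups) == 2

    def test_compatible_fragments_join(self):
        groups = enumerate_isoforms(_gene_with_chains([(1, 2), (2, 3)]))
        assert len(groups) == 1
        assert not chains_conflict((1, 2), (2, 3))

    def test_three_chain_attachment_is_deterministic(self):
        # (3,4) is compatible with both seeds; it attaches to the group
        # labelled by the smaller chain, (1,2,3)
        gene = _gene_with_chains([(1, 2, 3), (1, 3), (3, 4)])
        groups = enumerate_isoforms(gene)
        assert len(groups) == 2
        by_chain = {gene.assigned[c]: i for i, g in enumerate(groups)
                    for c in g}
        assert by_chain[(3, 4)] == by_chain[(1, 2, 3)]

    def test_conflict_matches_bruteforce_on_all_5exon_chain_pairs(self):
        chains = [c for r in range(1, 6)
                  for c in itertools.combinations(range(5), r)]
        for a in chains:
            for b in chains:
                assert chains_conflict(a, b) == conflict_bruteforce(a, b), \
                    (a, b)

    def test_grouping_invariant_to_insertion_order(self):
        chains = [(0, 1, 2, 3), (0, 2, 3), (1, 2), (3, 4), (0, 1)]
        base = enumerate_isoforms(_gene_with_chains(chains))
        base_sets = {frozenset(tuple(sorted(g)) for g in base)}
        for perm in itertools.permutations(range(len(chains))):
            gene = ConsensusGene("g", "chr1", "+",
                                 [(i * 100, i * 100 + 50) for i in range(10)])
            for i in perm:
                gene.assigned[f"c{i}"] = tuple(chains[i])
            groups = enumerate_isoforms(gene)
            names = {frozenset(tuple(sorted(
                tuple(sorted(chains[int(c[1:])])) for c in g)) for g in groups)}
            assert len(groups) == len(base)

    def test_subchain_never_increases_isoform_count(self):
        rng = random.Random(14)
        for _ in range(30):
            n = rng.randint(2, 5)
            chains = []
            for _ in range(rng.randint(1, 4)):
                size = rng.randint(1, n)
                chains.append(tuple(sorted(rng.sample(range(n), size))))
            before = len(enumerate_isoforms(_gene_with_chains(chains)))
            donor = rng.choice(chains)
            i = rng.randint(0, len(donor) - 1)
            j = rng.randint(i, len(donor) - 1)
            fragment = donor[i:j + 1]
            after = len(enumerate_isoforms(
                _gene_with_chains(chains + [fragment])))
            assert after <= before, (chains, fragment)


class TestUnigeneSelection:
    def _gene(self, lengths):
        gene = ConsensusGene("gA", "chr1", "+", [(0, 1000)])
        for cid in lengths:
            gene.assigned[cid] = (0,)
        return gene

    def test_longest_contig_selected(self):
        contigs = {"a": Contig("a", "A" * 500), "b": Contig("b", "A" * 800)}
        gene = self._gene(["a", "b"])
        (uni,) = select_unigenes({"gA": gene}, contigs)
        assert uni.id == "b" and gene.representative_id == "b"
        assert uni.description == "gene=gA"

    def test_single_contig_gene(self):
        contigs = {"a": Contig("a", "A" * 500)}
        (uni,) = select_unigenes({"gA": self._gene(["a"])}, contigs)
        assert uni.id == "a"

    def test_equal_lengths_take_smaller_id(self):
        contigs = {"b": Contig("b", "A" * 500), "a": Contig("a", "T" * 500)}
        (uni,) = select_unigenes({"gA": self._gene(["b", "a"])}, contigs)
        assert uni.id == "a"


class TestIsoformSummary:
    def test_basic_arithmetic(self):
        s = summarize_isoform_counts([1, 1, 2, 4])
        assert s.n_singlets == 2 and s.n_multi == 2
        assert s.multi_mean == pytest.approx(3.0)
        assert s.n_singlets + s.n_multi == s.n_genes

    def test_all_singlets_reports_absent_stats(self):
        s = summarize_isoform_counts([1, 1, 1])
        assert s.n_multi == 0
        assert s.multi_mean is None and s.multi_sd is None

    def test_range_over_multi_genes(self):
        s = summarize_isoform_counts([1, 2, 84])
        assert (s.multi_min, s.multi_max) == (2, 84)


def test_gene_model_gff3_round_trip(tmp_path):
    models = [GeneModel("g1", "chr1", "+", [(10, 110), (200, 260)]),
              GeneModel("g2", "chr2", "-", [(0, 90)])]
    p = tmp_path / "models.gff3"
    write_gene_models(models, p)
    back = read_gene_models(p)
    assert [(m.gene_id, m.target_id, m.strand, m.exons) for m in back] == \
           [(m.gene_id, m.target_id, m.strand, m.exons) for m in models]
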
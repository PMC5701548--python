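"""Overlap alignment and redundancy-collapse clustering."""

import random

import pytest

from transcurate.collapse import (collapse_contigs, dedup_proteins,
                                  pairwise_overlap)
from transcurate.seqio import Contig, revcomp


def rand_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def rand_aa(rng, n):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


def mutate_positions(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(out)


def dovetail_pair(rng, overlap_len, n_mismatch, flank=100):
    """a ends with the overlap; b starts with a mutated copy of it."""
    overlap = rand_nt(rng, overlap_len)
    positions = rng.sample(range(10, overlap_len - 10), n_mismatch)
    overlap_b = mutate_positions(rng, overlap, positions)
    a = rand_nt(rng, flank) + overlap
    b = overlap_b + rand_nt(rng, flank)
    return a, b


class TestPairwiseOverlap:
    @pytest.mark.parametrize("oracle", [True, False])
    def test_identical_sequences(self, oracle):
        rng = random.Random(0)
        s = rand_nt(rng, 200)
        ov = pairwise_overlap(s, s, oracle=oracle)
        assert ov.overlap_len == 200
        assert ov.identity == 100.0
        assert ov.orientation == "forward"

    @pytest.mark.parametrize("oracle", [True, False])
    def test_reverse_complement(self, oracle):
        rng = random.Random(1)
        s = rand_nt(rng, 200)
        ov = pairwise_overlap(s, revcomp(s), oracle=oracle)
        assert ov.identity == 100.0
        assert ov.orientation == "revcomp"

    @pytest.mark.parametrize("oracle", [True, False])
    def test_150_column_overlap_with_5_mismatches(self, oracle):
        # 145 matches over 150 aligned columns -> 96.67%
        rng = random.Random(2)
        a, b = dovetail_pair(rng, 150, 5)
        ov = pairwise_overlap(a, b, oracle=oracle)
        assert ov.overlap_len == 150
        assert round(ov.identity, 2) == 96.67

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_overlap("", "ACGT")


class TestCollapseContigs:
    def test_identical_pair_collapses(self):
        rng = random.Random(3)
        s = rand_nt(rng, 200)
        reps, cmap = collapse_contigs([Contig("a", s), Contig("b", s)])
        assert len(reps) == 1
        assert cmap.members[reps[0].id] == ["a", "b"]

    def test_150bp_overlap_at_96pct_collapses(self):
        rng = random.Random(4)
        a, b = dovetail_pair(rng, 150, 6)  # 144/150 = 96.0%
        reps, _ = collapse_contigs([Contig("a", a), Contig("b", b)])
        assert len(reps) == 1

    def test_80bp_perfect_overlap_kept_separate(self):
        rng = random.Random(5)
        a, b = dovetail_pair(rng, 80, 0)
        reps, _ = collapse_contigs([Contig("a", a), Contig("b", b)])
        assert len(reps) == 2

    def test_low_identity_overlap_kept_separate(self):
        rng = random.Random(6)
        a, b = dovetail_pair(rng, 150, 15)  # 90% < 95%
        reps, _ = collapse_contigs([Contig("a", a), Contig("b", b)])
        assert len(reps) == 2

    def test_representative_is_longest(self):
        rng = random.Random(7)
        core = rand_nt(rng, 300)
        contigs = [Contig("short", core[:220]), Contig("long", core)]
        reps, cmap = collapse_contigs(contigs)
        assert [r.id for r in reps] == ["long"]

    def test_conservation_and_idempotence(self, tiny_sim):
        contigs = tiny_sim.all_contigs()
        reps, cmap = collapse_contigs(contigs)
        members = [m for ms in cmap.members.values() for m in ms]
        assert sorted(members) == sorted(c.id for c in contigs)
        reps2, cmap2 = collapse_contigs(reps)
        assert sorted(r.id for r in reps2) == sorted(r.id for r in reps)
        assert all(len(m) == 1 for m in cmap2.members.values())

    def test_order_invariance(self, tiny_sim):
        contigs = tiny_sim.all_contigs()
        shuffled = list(contigs)
        random.Random(8).shuffle(shuffled)
        _, cmap_a = collapse_contigs(contigs)
        _, cmap_b = collapse_contigs(shuffled)
        assert cmap_a.cluster_sets() == cmap_b.cluster_sets()
        assert sorted(cmap_a.members) == sorted(cmap_b.members)

    def test_seeded_equals_oracle_clustering(self):
        rng = random.Random(9)
        contigs = []
        for i in range(12):
            base = rand_nt(rng, 300)
            contigs.append(Contig(f"s{i:02d}", base))
            if i % 3 == 0:  # planted near-duplicate
                mut = mutate_positions(rng, base,
                                       rng.sample(range(300), 6))
                contigs.append(Contig(f"s{i:02d}_dup", mut))
            if i % 4 == 0:  # planted reverse-complement copy
                contigs.append(Contig(f"s{i:02d}_rc", revcomp(base)))
        _, fast = collapse_contigs(contigs)
        _, slow = collapse_contigs(contigs, oracle=True)
        assert fast.cluster_sets() == slow.cluster_sets()


class TestDedupProteins:
    def test_identical_equal_length_keeps_smaller_id(self):
        rng = random.Random(10)
        s = rand_aa(rng, 120)
        reps, cmap = dedup_proteins([Contig("pB", s), Contig("pA", s)])
        assert [r.id for r in reps] == ["pA"]
        assert cmap.members["pA"] == ["pA", "pB"]

    def test_85pct_identity_pair_kept(self):
        rng = random.Random(11)
        s = rand_aa(rng, 100)
        out = list(s)
        for p in rng.sample(range(5, 95), 15):
            out[p] = rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY"
                                 if a != s[p]])
        reps, _ = dedup_proteins([Contig("a", s), Contig("b", "".join(out))])
        assert len(reps) == 2

    def test_short_overlap_fraction_kept(self):
        # perfect identity but overlap covers only half the shorter seq
        rng = random.Random(12)
        core = rand_aa(rng, 50)
        a = rand_aa(rng, 50) + core
        b = core + rand_aa(rng, 50)
        reps, _ = dedup_proteins([Contig("a", a), Contig("b", b)])
        assert len(reps) == 2

    def test_longest_representative(self):
        rng = random.Random(13)
        s = rand_aa(rng, 150)
        reps, _ = dedup_proteins([Contig("frag", s[:140]), Contig("full", s)])
        assert [r.id for r in reps] == ["full"]
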
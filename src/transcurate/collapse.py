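"""Redundancy collapse of contigs and reference proteins.

De novo assemblies run at several k-mer settings re-assemble the same
transcript many times, with small differences caused by SNP/indel
variation in the pooled RNA and by assembly error.  This module merges
such near-identical sequences: two sequences are mergeable when their
best overlap alignment meets both an overlap-length and an identity
threshold (100 bp / 95% for contigs; 90% of the shorter sequence / 90%
for reference proteins), clusters are the single-linkage transitive
closure of mergeability, and each cluster is represented by its longest
member.

Identity convention: matches divided by aligned columns, counting
internal gap columns in the denominator and excluding terminal
overhangs.  Nucleotide comparisons evaluate both orientations.

Two alignment routes are provided.  The default route seeds candidate
overlaps with shared exact k-mers (k=15 nt / 5 aa) and performs gapped
alignment of the implied overlap window with edlib; the ``oracle`` route
runs full dynamic-programming local alignment and exists as an
independent cross-check for the seeded path.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache

import edlib
from Bio import Align

from .seqio import Contig, revcomp

SEED_K_NT = 15
SEED_K_AA = 5
MAX_KMER_BUCKET = 200
DIAG_BAND = 32


@dataclass
class OverlapResult:
    a_id: str
    b_id: str
    overlap_len: int
    identity: float
    orientation: str  # "forward" | "revcomp"
    matches: int = 0


@dataclass
class ClusterMap:
    """Bidirectional cluster bookkeeping: every input id belongs to exactly
    one cluster and each representative is a member of its own cluster."""

    members: dict[str, list[str]] = field(default_factory=dict)
    representative_of: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_clusters(cls, clusters: dict[str, list[str]]) -> "ClusterMap":
        cm = cls()
        for rep, mem in clusters.items():
            cm.members[rep] = sorted(mem)
            for m in mem:
                cm.representative_of[m] = rep
        return cm

    def cluster_sets(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.members.values()}


# ---------------------------------------------------------------------------
# pairwise overlap alignment
# ---------------------------------------------------------------------------

def _oracle_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


def _oracle_overlap(a: str, b: str) -> tuple[int, int]:
    """(aligned columns, matches) of the best local alignment of a vs b."""
    al = _oracle_aligner()
    try:
        alignment = al.align(a, b)[0]
    except IndexError:
        return 0, 0
    c = alignment.counts()
    internal_gaps = (c.internal_insertions + c.internal_deletions
                     if hasattr(c, "internal_insertions") else c.gaps)
    columns = c.identities + c.mismatches + internal_gaps
    return int(columns), int(c.identities)


@lru_cache(maxsize=8192)
def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        d[seq[i:i + k]].append(i)
    return d


_rc_cached = lru_cache(maxsize=8192)(revcomp)


def _best_diagonal(a: str, b: str, k: int) -> int | None:
    """Most seed-supported diagonal (offset of a relative to b), with
    nearby diagonals pooled into bands to tolerate small indels."""
    idx = _kmer_positions(b, k)
    votes: Counter[int] = Counter()
    for i in range(len(a) - k + 1):
        for j in idx.get(a[i:i + k], ()):
            votes[i - j] += 1
    if not votes:
        return None
    band_votes: Counter[int] = Counter()
    for d, v in votes.items():
        band_votes[d // DIAG_BAND] += v
    band = band_votes.most_common(1)[0][0]
    in_band = {d: v for d, v in votes.items() if d // DIAG_BAND == band}
    return max(in_band, key=lambda d: (in_band[d], -abs(d)))


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(aligned columns, matches) from an edlib extended cigar."""
    columns = matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return columns, matches


def _seeded_overlap(a: str, b: str, k: int) -> tuple[int, int]:
    """(aligned columns, matches) of the overlap implied by the best
    shared-k-mer diagonal, refined by gapped (edlib) alignment."""
    d = _best_diagonal(a, b, k)
    if d is None:
        return 0, 0
    a_start, b_start = max(0, d), max(0, -d)
    span = min(len(a) - a_start, len(b) - b_start)
    if span < k:
        return 0, 0
    res = edlib.align(a[a_start:a_start + span], b[b_start:b_start + span],
                      mode="NW", task="path")
    return _cigar_stats(res["cigar"])


def pairwise_overlap(a: Contig | str, b: Contig | str,
                     mode: str = "nucleotide", oracle: bool = False,
                     k: int | None = None) -> OverlapResult:
    """Best-scoring overlap alignment between two sequences.

    Returns overlap length in aligned columns and percent identity over
    those columns.  In nucleotide mode both orientations are evaluated
    and the better one reported (ties favour forward).
    """
    a_id, a_seq = (a.id, a.seq) if isinstance(a, Contig) else ("a", a)
    b_id, b_seq = (b.id, b.seq) if isinstance(b, Contig) else ("b", b)
    if not a_seq or not b_seq:
        raise ValueError("pairwise_overlap requires non-empty sequences")
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    if k is None:
        k = SEED_K_NT if mode == "nucleotide" else SEED_K_AA
    compute = _oracle_overlap if oracle else (
        lambda x, y: _seeded_overlap(x, y, k))
    best = ("forward", *compute(a_seq, b_seq))  # orientation, columns, matches
    if mode == "nucleotide":
        # the reverse orientation cannot do meaningfully better when the
        # forward overlap is already near-perfect over the shorter sequence
        near_perfect = best[2] >= 0.95 * min(len(a_seq), len(b_seq))
        if oracle or not near_perfect:
            columns, matches = compute(a_seq, _rc_cached(b_seq))
            if matches > best[2]:
                best = ("revcomp", columns, matches)
    orient, columns, matches = best
    identity = 100.0 * matches / columns if columns else 0.0
    return OverlapResult(a_id, b_id, columns, identity, orient, matches)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, ids):
        self.parent = {i: i for i in ids}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _candidate_pairs(seqs: dict[str, str], k: int,
                     strand_aware: bool) -> set[tuple[str, str]]:
    """Pairs of ids sharing at least one exact k-mer (canonicalized over
    strands in nucleotide mode).  Highly repetitive k-mers are skipped."""
    index: dict[str, list[str]] = defaultdict(list)
    for sid in sorted(seqs):
        seq = seqs[sid]
        kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        if strand_aware:
            rc = revcomp(seq)
            kmers |= {rc[i:i + k] for i in range(len(rc) - k + 1)}
        for km in kmers:
            index[km].append(sid)
    pairs: set[tuple[str, str]] = set()
    # many k-mers index the same id group; deduplicate buckets first
    buckets = {tuple(ids) for ids in index.values()
               if 2 <= len(ids) <= MAX_KMER_BUCKET}
    for ids in buckets:
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                pairs.add((a, b) if a < b else (b, a))
    return pairs


def _cluster(records: list[Contig], mergeable, k: int,
             strand_aware: bool, all_pairs: bool) -> ClusterMap:
    seqs = {r.id: r.seq for r in records}
    if len(seqs) != len(records):
        raise ValueError("duplicate sequence ids in clustering input")
    ids = sorted(seqs)
    if all_pairs:
        pairs = {(ids[i], ids[j]) for i in range(len(ids))
                 for j in range(i + 1, len(ids))}
    else:
        pairs = _candidate_pairs(seqs, k, strand_aware)
    uf = _UnionFind(ids)
    for a, b in sorted(pairs):
        if uf.find(a) == uf.find(b):
            continue  # already joined; transitive closure unaffected
        if mergeable(seqs[a], seqs[b]):
            uf.union(a, b)
    groups: dict[str, list[str]] = defaultdict(list)
    for i in ids:
        groups[uf.find(i)].append(i)
    by_id = {r.id: r for r in records}
    clusters: dict[str, list[str]] = {}
    for mem in groups.values():
        rep = min(mem, key=lambda m: (-by_id[m].length, m))
        clusters[rep] = sorted(mem)
    return ClusterMap.from_clusters(clusters)


def collapse_contigs(contigs: list[Contig], min_overlap: int = 100,
                     min_identity: float = 95.0, oracle: bool = False
                     ) -> tuple[list[Contig], ClusterMap]:
    """Merge near-identical contigs across assemblies into a non-redundant
    set.

    Two contigs are mergeable iff their best overlap alignment spans at
    least ``min_overlap`` columns at >= ``min_identity`` percent identity
    (both orientations considered); clusters are the transitive closure of
    mergeability and each emits its longest member (ties: smallest id).
    """
    def mergeable(a: str, b: str) -> bool:
        ov = pairwise_overlap(a, b, mode="nucleotide", oracle=oracle)
        return ov.overlap_len >= min_overlap and ov.identity >= min_identity

    cmap = _cluster(contigs, mergeable, SEED_K_NT, strand_aware=True,
                    all_pairs=oracle)
    by_id = {c.id: c for c in contigs}
    reps = [by_id[rep] for rep in sorted(cmap.members)]
    for rep in reps:
        n = len(cmap.members[rep.id])
        if n > 1:
            rep.description = (rep.description + f" cluster_size={n}").strip()
    return reps, cmap


def dedup_proteins(proteins: list[Contig], min_identity: float = 90.0,
                   min_overlap_frac: float = 0.90, oracle: bool = False
                   ) -> tuple[list[Contig], ClusterMap]:
    """Deduplicate a reference protein set.

    A pair is mergeable iff identity >= ``min_identity`` and the aligned
    overlap covers >= ``min_overlap_frac`` of the *shorter* sequence;
    single-linkage clusters keep the longest member (ties: smallest id).
    """
    def mergeable(a: str, b: str) -> bool:
        ov = pairwise_overlap(a, b, mode="protein", oracle=oracle)
        need = min_overlap_frac * min(len(a), len(b))
        return ov.overlap_len >= need and ov.identity >= min_identity

    cmap = _cluster(proteins, mergeable, SEED_K_AA, strand_aware=False,
                    all_pairs=oracle)
    by_id = {p.id: p for p in proteins}
    reps = [by_id[rep] for rep in sorted(cmap.members)]
    return reps, cmap
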
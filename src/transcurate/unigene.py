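"""Isoform-to-gene grouping and unigene selection.

Contigs with biological evidence are spliced-aligned to the genome of a
related reference species; per reference gene, all spliced alignments
are combined into a consensus exon model, each contig is summarized as
its *exon chain* (the ordered set of consensus exons it covers), and
chains are grouped into isoforms: two chains conflict when, within their
shared genomic span, one skips a consensus exon the other includes.
Compatible fragments (e.g. two non-overlapping halves of one transcript)
join the same group, which is what lets non-overlapping contigs be
joined to the same reference gene.  The longest contig of each gene is
selected as the unigene — an EST-like, one-sequence-per-gene
representative set.

The internal spliced mapper (:func:`splice_map`) is an exact-k-mer
chaining aligner intended for synthetic, high-identity data; mapping
diverged transcripts across a deep species split is a job for a real
spliced aligner whose GFF3 output this module also consumes.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .seqio import (Contig, SplicedAlignment, _parse_gff3_line, revcomp)

logger = logging.getLogger(__name__)

MAP_K = 21           # exact seed length of the internal spliced mapper
_MAX_SEED_HITS = 50  # skip k-mers more repetitive than this
_SAME_DIAG_GAP = 64  # bp; same-diagonal runs closer than this are bridged


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A reference gene: ordered disjoint exon intervals (0-based
    half-open) on one genome sequence."""

    gene_id: str
    target_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id!r} has overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features with ``exon``
    children, optionally through an ``mRNA`` level)."""
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = _parse_gff3_line(line, lineno, path)
            fid = feat["attrs"].get("ID")
            if feat["type"] == "gene":
                if fid is None:
                    raise ValueError(f"{path}: line {lineno}: gene without ID")
                genes[fid] = feat
            elif feat["type"] == "mRNA":
                parent_of[fid] = feat["attrs"].get("Parent", fid)
            elif feat["type"] == "exon":
                pid = feat["attrs"].get("Parent")
                if pid is None:
                    raise ValueError(f"{path}: line {lineno}: exon without Parent")
                gid = parent_of.get(pid, pid)
                exons[gid].append((feat["start"] - 1, feat["end"]))
    models = []
    for gid in sorted(genes):
        feat = genes[gid]
        ex = exons.get(gid)
        if not ex:
            raise ValueError(f"{path}: gene {gid!r} has no exon features")
        models.append(GeneModel(gid, feat["seqid"], feat["strand"],
                                sorted(set(ex))))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write("\t".join([m.target_id, "transcurate", "gene", str(s + 1),
                                str(e), ".", m.strand, ".", f"ID={m.gene_id}"])
                     + "\n")
            for i, (xs, xe) in enumerate(m.exons, start=1):
                fh.write("\t".join([m.target_id, "transcurate", "exon",
                                    str(xs + 1), str(xe), ".", m.strand, ".",
                                    f"ID={m.gene_id}.e{i};Parent={m.gene_id}"])
                         + "\n")


def _check_models_disjoint(models: list[GeneModel]) -> None:
    by_target: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_target[m.target_id].append(m)
    for tgt, ms in by_target.items():
        ms = sorted(ms, key=lambda m: m.span)
        for a, b in zip(ms, ms[1:]):
            if b.span[0] < a.span[1]:
                raise ValueError(f"gene models {a.gene_id!r} and {b.gene_id!r} "
                                 f"overlap on {tgt!r}; overlapping reference "
                                 f"models are rejected")


# ---------------------------------------------------------------------------
# internal spliced mapper (synthetic/test path)
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over one or more genome sequences."""

    def __init__(self, genome: dict[str, str], k: int = MAP_K):
        self.k = k
        self.genome = {t: s.upper() for t, s in genome.items()}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tgt in sorted(self.genome):
            seq = self.genome[tgt]
            for i in range(len(seq) - k + 1):
                self.index[seq[i:i + k]].append((tgt, i))


def _blocks_one_strand(seq: str, index: GenomeIndex
                       ) -> dict[str, list[tuple[int, int, int, int, float]]]:
    """Merge seed hits into identity-scored blocks, per target."""
    k = index.k
    runs: dict[tuple[str, int], list[int]] = defaultdict(list)  # (tgt,diag)->cpos
    for i in range(len(seq) - k + 1):
        hits = index.index.get(seq[i:i + k])
        if not hits or len(hits) > _MAX_SEED_HITS:
            continue
        for tgt, g in hits:
            runs[(tgt, g - i)].append(i)
    blocks: dict[str, list[tuple[int, int, int, int, float]]] = defaultdict(list)
    for (tgt, diag), cps in runs.items():
        cps.sort()
        start = prev = cps[0]
        segments = []
        for c in cps[1:]:
            if c - prev <= _SAME_DIAG_GAP:
                prev = c
            else:
                segments.append((start, prev + k))
                start = prev = c
        segments.append((start, prev + k))
        gseq = index.genome[tgt]
        for cs, ce in segments:
            gs, ge = cs + diag, ce + diag
            n = ce - cs
            matches = sum(a == b for a, b in zip(seq[cs:ce], gseq[gs:ge]))
            blocks[tgt].append((gs, ge, cs, ce, 100.0 * matches / n))
    return blocks


def _chain_blocks(blocks: list[tuple[int, int, int, int, float]],
                  slack: int = MAP_K
                  ) -> list[tuple[int, int, int, int, float]]:
    """Best colinear chain (increasing contig and genome coordinates),
    maximizing identity-weighted bases.

    Seed runs can overrun a splice junction by a few chance-matching
    bases, so consecutive blocks may overlap by up to ``slack`` on either
    axis; such overlaps are trimmed off the earlier block afterwards."""
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b[2], b[0]))
    n = len(blocks)
    weight = [(b[1] - b[0]) * b[4] for b in blocks]
    best = list(weight)
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            if (blocks[i][3] - blocks[j][2] <= slack
                    and blocks[i][1] - blocks[j][0] <= slack
                    and blocks[i][2] < blocks[j][2]
                    and blocks[i][0] < blocks[j][0]
                    and best[i] + weight[j] > best[j]):
                best[j] = best[i] + weight[j]
                prev[j] = i
    j = max(range(n), key=lambda x: best[x])
    chain = []
    while j != -1:
        chain.append(blocks[j])
        j = prev[j]
    chain = chain[::-1]
    trimmed = []
    for idx, blk in enumerate(chain):
        gs, ge, cs, ce, ident = blk
        if idx + 1 < len(chain):
            nxt = chain[idx + 1]
            cut = max(ce - nxt[2], ge - nxt[0], 0)
            ge, ce = ge - cut, ce - cut
        if ge > gs and ce > cs:
            trimmed.append((gs, ge, cs, ce, ident))
    return trimmed


def splice_map(contig: Contig, genome: dict[str, str] | GenomeIndex,
               k: int = MAP_K) -> SplicedAlignment | None:
    """Spliced-align a contig to the genome by exact-k-mer chaining.

    Both orientations are tried and the one with more identity-weighted
    matched bases wins (ties favour forward).  Returns ``None`` when no
    seed chain is found.  For minus-strand alignments the block contig
    coordinates refer to the reverse complement of the contig.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    best_aln: SplicedAlignment | None = None
    best_score = 0.0
    for strand, seq in (("+", contig.seq), ("-", revcomp(contig.seq))):
        per_target = _blocks_one_strand(seq, index)
        for tgt in sorted(per_target):
            chain = _chain_blocks(per_target[tgt])
            if not chain:
                continue
            score = sum((ge - gs) * ident / 100.0
                        for gs, ge, _, _, ident in chain)
            if score > best_score:
                total = sum(ge - gs for gs, ge, _, _, _ in chain)
                aln = SplicedAlignment(contig_id=contig.id, target_id=tgt,
                                       strand=strand, blocks=chain)
                aln.total_identity = 100.0 * score / total
                best_aln, best_score = aln, score
    return best_aln


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_to_genes(alignments: list[SplicedAlignment],
                    models: list[GeneModel]
                    ) -> tuple[dict[str, list[str]], list[str]]:
    """Assign each aligned contig to the reference gene whose exons it
    matches best.

    The score of (contig, gene) is the sum over alignment blocks of
    identity-weighted bases overlapping the gene's exons; each contig
    goes to the argmax gene (exact ties: smallest gene_id, logged).
    Returns (gene_id -> contig ids, unassigned contig ids).
    """
    _check_models_disjoint(models)
    by_target: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_target[m.target_id].append(m)
    for tgt in by_target:
        by_target[tgt].sort(key=lambda m: m.span)
    starts = {tgt: [m.span[0] for m in ms] for tgt, ms in by_target.items()}
    assigned: dict[str, list[str]] = defaultdict(list)
    unassigned: list[str] = []
    for aln in sorted(alignments, key=lambda a: a.contig_id):
        scores: dict[str, float] = defaultdict(float)
        ms = by_target.get(aln.target_id, [])
        for gs, ge, _, _, ident in aln.blocks:
            lo = bisect_right(starts.get(aln.target_id, []), gs) - 1
            for m in ms[max(lo, 0):]:
                if m.span[0] >= ge:
                    break
                ov = sum(_overlap((gs, ge), ex) for ex in m.exons)
                if ov:
                    scores[m.gene_id] += ov * ident / 100.0
        if not scores:
            unassigned.append(aln.contig_id)
            continue
        best = max(scores.values())
        winners = sorted(g for g, s in scores.items() if s == best)
        if len(winners) > 1:
            logger.info("contig %s ties between genes %s; assigned to %s",
                        aln.contig_id, winners, winners[0])
        assigned[winners[0]].append(aln.contig_id)
    return dict(assigned), unassigned


# ---------------------------------------------------------------------------
# consensus exon model and isoform chains
# ---------------------------------------------------------------------------

@dataclass
class ConsensusGene:
    gene_id: str
    target_id: str
    strand: str
    consensus_exons: list[tuple[int, int]]
    assigned: dict[str, tuple[int, ...]] = field(default_factory=dict)
    isoform_groups: list[list[str]] = field(default_factory=list)
    representative_id: str | None = None

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_groups)


def _snap(value: int, boundaries: list[int], tol: int) -> int:
    if tol <= 0 or not boundaries:
        return value
    nearest = min(boundaries, key=lambda b: abs(b - value))
    return nearest if abs(nearest - value) <= tol else value


def _union_intervals(intervals) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_consensus(gene_id: str, alignments: list[SplicedAlignment],
                    model: GeneModel, tol: int = 6) -> ConsensusGene:
    """Merge the reference exon model with all assigned alignments.

    Block boundaries within ``tol`` nt of a model exon boundary are
    snapped to it (absorbing aligner jitter); the consensus exons are the
    interval union of model exons and snapped blocks.  Each contig's exon
    chain (indices of consensus exons it covers) is recorded.
    """
    bounds = sorted({b for ex in model.exons for b in ex})
    snapped: dict[str, list[tuple[int, int]]] = {}
    for aln in alignments:
        ivs = []
        for gs, ge, _, _, _ in aln.blocks:
            s, e = _snap(gs, bounds, tol), _snap(ge, bounds, tol)
            if e > s:
                ivs.append((s, e))
        snapped[aln.contig_id] = _union_intervals(ivs)
    consensus = _union_intervals(
        list(model.exons) + [iv for ivs in snapped.values() for iv in ivs])
    gene = ConsensusGene(gene_id, model.target_id, model.strand, consensus)
    for cid in sorted(snapped):
        chain = tuple(i for i, ex in enumerate(consensus)
                      if any(_overlap(ex, iv) for iv in snapped[cid]))
        gene.assigned[cid] = chain
    return gene


def chains_conflict(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
    """Two exon chains conflict iff, restricted to their shared span of
    consensus exon indices, one skips an exon the other includes."""
    if not a or not b:
        return False
    lo = max(a[0], b[0])
    hi = min(a[-1], b[-1])
    if lo > hi:
        return False  # disjoint spans: compatible fragments
    sa = {i for i in a if lo <= i <= hi}
    sb = {i for i in b if lo <= i <= hi}
    return sa != sb


def enumerate_isoforms(consensus: ConsensusGene, tol: int = 6
                       ) -> list[list[str]]:
    """Group assigned contigs into isoforms by chain compatibility.

    Distinct chains are processed longest first (ties: lexicographically
    smallest).  A chain compatible with every chain already in a group
    may join it; when several groups qualify it attaches to the largest
    (then the one with the smallest label chain), which is deterministic
    and conservative (fewest isoforms).  A chain conflicting with every
    group seeds a new one.
    """
    del tol  # snapping already happened in build_consensus
    by_chain: dict[tuple[int, ...], list[str]] = defaultdict(list)
    for cid, chain in consensus.assigned.items():
        if chain:
            by_chain[chain].append(cid)
    groups: list[dict] = []  # {"chains": [...], "label": chain}
    for chain in sorted(by_chain, key=lambda c: (-len(c), c)):
        candidates = [g for g in groups
                      if all(not chains_conflict(chain, c) for c in g["chains"])]
        if candidates:
            tgt = min(candidates,
                      key=lambda g: (-sum(len(by_chain[c]) for c in g["chains"]),
                                     g["label"]))
            tgt["chains"].append(chain)
        else:
            groups.append({"chains": [chain], "label": chain})
    result = []
    for g in sorted(groups, key=lambda g: g["label"]):
        members = sorted(cid for c in g["chains"] for cid in by_chain[c])
        result.append(members)
    consensus.isoform_groups = result
    return result


def select_unigenes(consensus_genes: dict[str, ConsensusGene],
                    contigs_by_id: dict[str, Contig]) -> list[Contig]:
    """One representative contig per gene: the longest assigned contig
    (ties: smallest contig id); headers carry the gene id."""
    unigenes = []
    for gid in sorted(consensus_genes):
        gene = consensus_genes[gid]
        if not gene.assigned:
            continue
        rep_id = min(gene.assigned,
                     key=lambda c: (-contigs_by_id[c].length, c))
        gene.representative_id = rep_id
        rep = contigs_by_id[rep_id]
        unigenes.append(Contig(id=rep.id, seq=rep.seq, source=rep.source,
                               description=f"gene={gid}"))
    return unigenes


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class IsoformSummary:
    n_genes: int
    n_singlets: int
    n_multi: int
    distribution: dict[int, int]
    multi_mean: float | None
    multi_sd: float | None
    multi_min: int | None
    multi_max: int | None

    @property
    def pct_multi(self) -> float:
        return 100.0 * self.n_multi / self.n_genes if self.n_genes else 0.0


def summarize_isoform_counts(counts: list[int]) -> IsoformSummary:
    """Summary statistics over per-gene isoform counts; the mean/sd/range
    are over multi-isoform genes only (sd is the sample sd)."""
    counts = [int(c) for c in counts]
    multi = [c for c in counts if c >= 2]
    dist: dict[int, int] = {}
    for c in sorted(counts):
        dist[c] = dist.get(c, 0) + 1
    if multi:
        arr = np.asarray(multi, dtype=float)
        sd = float(arr.std(ddof=1)) if len(multi) > 1 else 0.0
        stats = (float(arr.mean()), sd, int(arr.min()), int(arr.max()))
    else:
        stats = (None, None, None, None)
    return IsoformSummary(
        n_genes=len(counts), n_singlets=len(counts) - len(multi),
        n_multi=len(multi), distribution=dist,
        multi_mean=stats[0], multi_sd=stats[1],
        multi_min=stats[2], multi_max=stats[3])


def isoform_summary(consensus_genes: dict[str, ConsensusGene]) -> IsoformSummary:
    counts = [g.n_isoforms for g in consensus_genes.values() if g.assigned]
    return summarize_isoform_counts(counts)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def group_genes(alignments: list[SplicedAlignment], models: list[GeneModel],
                tol: int = 6) -> tuple[dict[str, ConsensusGene], list[str]]:
    """Full grouping pass: assignment, consensus, isoform enumeration.

    Returns (gene_id -> ConsensusGene for genes with >=1 assigned contig,
    unplaced contig ids)."""
    assigned, unplaced = assign_to_genes(alignments, models)
    aln_by_id = {a.contig_id: a for a in alignments}
    model_by_id = {m.gene_id: m for m in models}
    out: dict[str, ConsensusGene] = {}
    for gid in sorted(assigned):
        gene = build_consensus(gid, [aln_by_id[c] for c in assigned[gid]],
                               model_by_id[gid], tol=tol)
        enumerate_isoforms(gene, tol=tol)
        out[gid] = gene
    return out, unplaced
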
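"""Assembly statistics and reference-proteome coverage evaluation.

Assemblies are ranked not by contig length statistics alone but by how
completely their contigs tile a trusted reference protein set: for each
reference protein we take the union of subject intervals of all passing
translated hits and bin proteins by the covered fraction, with special
interest in the >=90%-covered ("near full length") class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import AlignmentHit, Contig


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    mean_len: float
    median_len: float
    n50: int
    pct_n: float
    length_histogram: dict[str, int]


@dataclass
class CoverageRecord:
    protein_id: str
    protein_len: int
    covered_aa: int
    coverage_frac: float
    n_supporting_contigs: int


_HIST_EDGES = (0, 200, 500, 1000, 2000, 5000)


def n50(lengths) -> int:
    """Largest length L such that contigs of length >= L hold at least
    half of the total assembled bases (ties resolved to the largest L)."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def assembly_stats(contigs: list[Contig]) -> AssemblyStats:
    if not contigs:
        raise ValueError("assembly_stats requires a non-empty contig collection")
    lengths = np.array([c.length for c in contigs], dtype=np.int64)
    total = int(lengths.sum())
    non_atgc = sum(c.length - sum(c.seq.count(b) for b in "ACGT") for c in contigs)
    hist: dict[str, int] = {}
    edges = list(_HIST_EDGES) + [None]
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"{lo}-{hi - 1}" if hi is not None else f">={lo}"
        if hi is not None:
            hist[label] = int(((lengths >= lo) & (lengths < hi)).sum())
        else:
            hist[label] = int((lengths >= lo).sum())
    return AssemblyStats(
        n_contigs=len(contigs),
        total_bp=total,
        mean_len=float(lengths.mean()),
        median_len=float(np.median(lengths)),
        n50=n50(lengths),
        pct_n=100.0 * non_atgc / total,
        length_histogram=hist,
    )


def interval_union_size(intervals) -> int:
    """Total length of the union of 0-based half-open intervals."""
    ivs = sorted(intervals)
    covered = 0
    cur_start = cur_end = None
    for s, e in ivs:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def protein_coverage(hits: list[AlignmentHit], proteins: list[Contig],
                     min_identity: float = 50.0, min_aln_aa: int = 50,
                     aggregate: str = "union") -> list[CoverageRecord]:
    """Per-protein coverage by passing translated hits.

    A hit passes if it meets both the identity and alignment-length
    minima.  ``aggregate="union"`` (default) pools subject intervals over
    all passing contigs; ``aggregate="best"`` keeps only the single
    best-covering contig per protein, for sensitivity analysis.
    """
    if aggregate not in ("union", "best"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    plen = {p.id: p.length for p in proteins}
    by_protein: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for h in hits:
        if h.subject_id not in plen:
            raise ValueError(f"hit references unknown protein {h.subject_id!r}")
        if h.pct_identity < min_identity or h.aln_len < min_aln_aa:
            continue
        by_protein.setdefault(h.subject_id, {}).setdefault(
            h.query_id, []).append((h.s_start - 1, h.s_end))
    records = []
    for pid in sorted(plen):
        per_contig = by_protein.get(pid, {})
        if not per_contig:
            records.append(CoverageRecord(pid, plen[pid], 0, 0.0, 0))
            continue
        if aggregate == "union":
            all_ivs = [iv for ivs in per_contig.values() for iv in ivs]
            covered = interval_union_size(all_ivs)
        else:
            covered = max(interval_union_size(ivs) for ivs in per_contig.values())
        covered = min(covered, plen[pid])
        records.append(CoverageRecord(pid, plen[pid], covered,
                                      covered / plen[pid], len(per_contig)))
    return records


def coverage_bins(profile: list[CoverageRecord],
                  edges: list[float] = (0.5, 0.9)) -> dict[str, int]:
    """Count proteins per coverage class.

    Classes are half-open ``[e_i, e_{i+1})`` with a closed top class
    ``[e_last, 1.0]`` and a ``<e_0`` class below the first edge, so the
    >=90% class (the headline near-full-length count) uses a closed lower
    bound.
    """
    edges = list(edges)
    if any(not 0 < e <= 1 for e in edges):
        raise ValueError("coverage bin edges must lie in (0, 1]")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("coverage bin edges must be strictly increasing")
    labels = [f"<{edges[0]:g}"]
    labels += [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
    labels += [f">={edges[-1]:g}"]
    counts = {lab: 0 for lab in labels}
    for rec in profile:
        f = rec.coverage_frac
        if f < edges[0]:
            counts[labels[0]] += 1
        elif f >= edges[-1]:
            counts[labels[-1]] += 1
        else:
            for (a, b), lab in zip(zip(edges, edges[1:]), labels[1:-1]):
                if a <= f < b:
                    counts[lab] += 1
                    break
    return counts
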
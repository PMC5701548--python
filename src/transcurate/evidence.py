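"""Evidence-based contig partitioning.

Length-filtered contigs are classified by their translated-search hits
against annotated proteomes into four disjoint classes: contigs hitting
known micro-organisms (viruses, bacteria, fungi) are screened out first
as exogenous material; the remainder are called ant genes if they hit an
ant proteome, other-insect genes if they only hit a non-ant insect, and
unannotated otherwise.  A hit counts as evidence when it passes all
three thresholds at once: e-value <= 1e-3, amino-acid identity >= 70%
and alignment length >= 33 residues (100 bases).  All minima are
inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .config import PipelineConfig
from .seqio import AlignmentHit, Contig

logger = logging.getLogger(__name__)

CLASSES = ("ant", "other_insect", "microorganism", "unannotated")
_PRECEDENCE = ("microorganism", "ant", "other_insect")


@dataclass
class EvidencePartition:
    """Disjoint classification of length-passing contigs."""

    class_of: dict[str, str]
    dropped_short: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in CLASSES}
        for cls in self.class_of.values():
            c[cls] += 1
        return c

    def ids_in(self, cls: str) -> set[str]:
        return {cid for cid, c in self.class_of.items() if c == cls}


def length_filter(contigs: list[Contig], min_len: int = 200
                  ) -> tuple[list[Contig], list[Contig]]:
    """Split contigs at a length floor (kept iff length >= min_len),
    preserving input order on both sides."""
    kept = [c for c in contigs if c.length >= min_len]
    dropped = [c for c in contigs if c.length < min_len]
    return kept, dropped


def hit_passes(hit: AlignmentHit, cfg: PipelineConfig, units: str = "aa") -> bool:
    min_len = cfg.evidence_min_aln_aa if units == "aa" else cfg.evidence_min_aln_nt
    return (hit.evalue <= cfg.evidence_max_evalue
            and hit.pct_identity >= cfg.evidence_min_identity
            and hit.aln_len >= min_len)


def classify_contigs(contigs: list[Contig], hits: list[AlignmentHit],
                     taxa: dict[str, str], cfg: PipelineConfig | None = None,
                     units: str = "aa", best_hit_wins: bool = False,
                     dropped_short: list[str] | None = None
                     ) -> EvidencePartition:
    """Assign each contig to an evidence class.

    Default precedence follows the published screening order: any passing
    micro-organism hit wins (exogenous material is removed first), then
    any passing ant hit, then other insects; contigs with no passing hit
    are unannotated.  ``best_hit_wins=True`` instead classifies by the
    highest-bitscore passing hit.
    """
    cfg = cfg or PipelineConfig()
    known = {c.id for c in contigs}
    passing: dict[str, list[tuple[str, float]]] = {}
    for h in hits:
        if h.query_id not in known:
            raise ValueError(f"hit references contig {h.query_id!r} absent "
                             f"from the input")
        if not hit_passes(h, cfg, units):
            continue
        taxon = taxa.get(h.subject_id)
        if taxon is None:
            warnings.warn(f"subject {h.subject_id!r} missing from taxon map; "
                          f"treated as 'other'", stacklevel=2)
            taxon = "other"
        passing.setdefault(h.query_id, []).append((taxon, h.bitscore))
    class_of: dict[str, str] = {}
    for c in contigs:
        evid = passing.get(c.id, [])
        if best_hit_wins and evid:
            taxon = max(evid, key=lambda tv: tv[1])[0]
            class_of[c.id] = taxon if taxon in _PRECEDENCE else "unannotated"
            continue
        taxa_seen = {t for t, _ in evid}
        for cls in _PRECEDENCE:
            if cls in taxa_seen:
                class_of[c.id] = cls
                break
        else:
            class_of[c.id] = "unannotated"
    return EvidencePartition(class_of=class_of,
                             dropped_short=list(dropped_short or []))


def round_half_up(x: float, dp: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{dp}"),
                                           rounding=ROUND_HALF_UP))


def partition_report(partition: EvidencePartition) -> list[dict]:
    """Labelled counts and percentages (half-up, one decimal) over the
    length-passing total, plus a total row."""
    total = len(partition.class_of)
    if total == 0:
        raise ValueError("partition_report requires a non-empty partition")
    counts = partition.counts()
    rows = []
    for cls in CLASSES:
        rows.append({"class": cls, "count": counts[cls],
                     "percent": round_half_up(100.0 * counts[cls] / total, 1)})
    rows.append({"class": "total", "count": total, "percent": 100.0})
    return rows
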
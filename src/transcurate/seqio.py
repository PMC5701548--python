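"""Readers and writers for the formats the curation pipeline touches.

Conventions
-----------
* All *internal* interval arithmetic is 0-based half-open.  Conversion to
  and from the 1-based inclusive coordinates of GFF3 and tabular alignment
  files happens only here, at the I/O boundary.
* FASTA record ids are the first whitespace-delimited token of the header;
  the remainder is kept as a description.
* Minus-strand tabular hits are normalized (start <= end) with an explicit
  strand flag rather than swapped-in-place coordinates, so that interval
  unions can be taken directly.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import unquote

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTUNRYSWKMBDHV")
IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """A nucleotide consensus sequence from one assembly.

    ``source`` carries an assembly label (k-mer tag or caste tag) and is
    preserved through collapse so that per-source provenance survives
    redundancy removal.
    """

    id: str
    seq: str
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One row of a 12-column tabular local-alignment result.

    ``aln_len`` is in alignment columns: amino acids for translated
    searches, nucleotides otherwise.  Coordinates are 1-based inclusive as
    in the file; reversed coordinate pairs are normalized at parse time
    with the orientation recorded in ``strand``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    strand: str = "+"


@dataclass
class SplicedAlignment:
    """A contig's exon-block alignment to a reference genome.

    ``blocks`` is an ordered list of
    ``(genome_start, genome_end, contig_start, contig_end, block_identity)``
    tuples in internal 0-based half-open coordinates, sorted and
    non-overlapping along the genome.  For minus-strand alignments the
    contig coordinates refer to the reverse-complemented contig, so they
    ascend together with the genome coordinates.
    """

    contig_id: str
    target_id: str
    strand: str
    blocks: list[tuple[int, int, int, int, float]]
    total_identity: float = 100.0

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b[0])
        prev_end = -1
        for gs, ge, cs, ce, _ident in self.blocks:
            if ge - gs < 1 or ce - cs < 1:
                raise ValueError(
                    f"alignment of {self.contig_id!r}: block length < 1")
            if gs < prev_end:
                raise ValueError(
                    f"alignment of {self.contig_id!r}: overlapping blocks on genome")
            prev_end = ge

    @property
    def genome_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def matched_bases(self) -> float:
        return sum((ge - gs) * ident / 100.0 for gs, ge, _, _, ident in self.blocks)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_fasta_characters(path: Path, alphabet: set[str], label: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith((">", ";")):
                continue
            bad = set(line.upper()) - alphabet - {"-", "."}
            if bad:
                raise ValueError(
                    f"{path}: non-IUPAC {label} character(s) "
                    f"{sorted(bad)} at line {lineno}")


def read_fasta(path: str | Path, alphabet: str = "nucleotide",
               source: str = "") -> list[Contig]:
    """Read a FASTA file into :class:`Contig` records.

    ``alphabet`` is ``"nucleotide"`` or ``"protein"``; sequences are
    validated against the corresponding IUPAC code set and uppercased.
    Duplicate ids and non-IUPAC characters are hard errors; an empty file
    yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    charset = IUPAC_NT if alphabet == "nucleotide" else IUPAC_AA
    _validate_fasta_characters(path, charset, alphabet)
    records: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(Contig(id=rec.id, seq=str(rec.seq).upper(),
                              source=source, description=desc))
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# 12-column BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLS = ("qseqid sseqid pident length mismatch gapopen "
               "qstart qend sstart send evalue bitscore").split()


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file (BLAST ``-outfmt 6``).

    Reversed coordinate pairs (start > end) are normalized; a single
    reversal on either side is recorded as minus strand.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated test fixtures
                fields = line.split()
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: row {rowno}: expected 12 columns, got {len(fields)}")
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                mism = int(fields[4])
                gaps = int(fields[5])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: row {rowno}: unparsable numeric field "
                                 f"({exc})") from None
            if not 0 <= pident <= 100:
                raise ValueError(f"{path}: row {rowno}: pident {pident} out of [0,100]")
            if evalue < 0:
                raise ValueError(f"{path}: row {rowno}: negative e-value")
            strand = "+"
            if qs > qe:
                qs, qe = qe, qs
                strand = "-" if strand == "+" else "+"
            if ss > se:
                ss, se = se, ss
                strand = "-" if strand == "+" else "+"
            hits.append(AlignmentHit(fields[0], fields[1], pident, aln_len, mism,
                                     gaps, qs, qe, ss, se, evalue, bits, strand))
    return hits


def write_blast_tab(hits, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ss, se = (h.s_start, h.s_end) if h.strand == "+" else (h.s_end, h.s_start)
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, ss, se,
                f"{h.evalue:.2g}", f"{h.bitscore:.1f}")) + "\n")


# ---------------------------------------------------------------------------
# GFF3 spliced alignments (match / match_part dialect)
# ---------------------------------------------------------------------------

PARENT_TYPES = {"match", "cDNA_match", "EST_match"}


def _parse_gff3_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for item in col9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[unquote(k)] = unquote(v)
    return attrs


def _parse_gff3_line(line: str, lineno: int, path) -> dict:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns, "
                         f"got {len(cols)}")
    return {
        "seqid": cols[0], "source": cols[1], "type": cols[2],
        "start": int(cols[3]), "end": int(cols[4]), "score": cols[5],
        "strand": cols[6], "phase": cols[7],
        "attrs": _parse_gff3_attributes(cols[8]), "lineno": lineno,
    }


def _target_to_contig_interval(feat, path) -> tuple[str, int, int]:
    tgt = feat["attrs"].get("Target")
    if tgt is None:
        fid = feat["attrs"].get("ID") or feat["attrs"].get("Parent") or "?"
        raise ValueError(f"{path}: line {feat['lineno']}: feature {fid!r} "
                         f"({feat['type']}) lacks a Target attribute")
    parts = tgt.split()
    if len(parts) < 3:
        raise ValueError(f"{path}: line {feat['lineno']}: malformed Target {tgt!r}")
    return parts[0], int(parts[1]) - 1, int(parts[2])


def _block_identity(feat) -> float:
    for key in ("Identity", "identity"):
        if key in feat["attrs"]:
            v = float(feat["attrs"][key])
            return v * 100.0 if v <= 1.0 else v
    return 100.0


def read_spliced_gff3(path: str | Path) -> list[SplicedAlignment]:
    """Read spliced alignments from GFF3.

    Two common dialects are accepted: ``match`` / ``cDNA_match`` /
    ``EST_match`` parents with ``match_part`` children carrying ``Target``
    attributes, and multi-line ``cDNA_match`` features sharing an ``ID``
    where each line is one block.  1-based inclusive file coordinates are
    converted to internal 0-based half-open on read.
    """
    path = Path(path)
    parents: dict[str, list[dict]] = {}
    parent_order: list[str] = []
    children: dict[str, list[dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = _parse_gff3_line(line, lineno, path)
            if feat["type"] in PARENT_TYPES:
                fid = feat["attrs"].get("ID")
                if fid is None:
                    raise ValueError(f"{path}: line {lineno}: {feat['type']} "
                                     f"feature without ID")
                if fid not in parents:
                    parents[fid] = []
                    parent_order.append(fid)
                parents[fid].append(feat)
            elif feat["type"] == "match_part":
                pid = feat["attrs"].get("Parent")
                if pid is None:
                    raise ValueError(f"{path}: line {lineno}: match_part "
                                     f"without Parent attribute")
                children.setdefault(pid, []).append(feat)
    orphans = set(children) - set(parents)
    if orphans:
        raise ValueError(f"{path}: match_part children reference unknown "
                         f"parent(s) {sorted(orphans)}")
    alignments = []
    for pid in parent_order:
        feats = children.get(pid) or parents[pid]
        anchor = parents[pid][0]
        blocks = []
        contig_id = None
        for feat in sorted(feats, key=lambda f: f["start"]):
            cid, cs, ce = _target_to_contig_interval(feat, path)
            contig_id = contig_id or cid
            blocks.append((feat["start"] - 1, feat["end"], cs, ce,
                           _block_identity(feat)))
        aln = SplicedAlignment(
            contig_id=contig_id, target_id=anchor["seqid"],
            strand=anchor["strand"] if anchor["strand"] in "+-" else "+",
            blocks=blocks)
        idents = [b[4] for b in aln.blocks]
        aln.total_identity = sum(
            (ge - gs) * i for (gs, ge, _, _, _), i in zip(aln.blocks, idents)
        ) / sum(ge - gs for gs, ge, _, _, _ in aln.blocks)
        alignments.append(aln)
    return alignments


def write_spliced_gff3(alignments, path: str | Path) -> None:
    """Serialize spliced alignments back to 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, aln in enumerate(alignments):
            fid = f"aln{i:06d}"
            gs, ge = aln.genome_span
            fh.write("\t".join([
                aln.target_id, "transcurate", "match", str(gs + 1), str(ge),
                ".", aln.strand, ".", f"ID={fid};Target={aln.contig_id}"]) + "\n")
            for (bgs, bge, bcs, bce, ident) in aln.blocks:
                fh.write("\t".join([
                    aln.target_id, "transcurate", "match_part",
                    str(bgs + 1), str(bge), ".", aln.strand, ".",
                    f"Parent={fid};Target={aln.contig_id} {bcs + 1} {bce};"
                    f"Identity={ident:.2f}"]) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_taxa(path: str | Path) -> dict[str, str]:
    """Read a two/three-column subject-id -> taxon-class table."""
    taxa: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least "
                                 f"2 tab-separated columns")
            if fields[0] == "subject_id":  # header
                continue
            taxa[fields[0]] = fields[1]
    return taxa


def write_report(rows: list[dict], path: str | Path, format: str = "tsv",
                 float_dp: int = 3) -> None:
    """Write labelled rows deterministically (sorted by the first key).

    Floats are rendered with ``float_dp`` decimal places so that repeated
    runs produce byte-identical files.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    path = Path(path)
    if not rows:
        warnings.warn(f"{path}: writing header-only/empty report", stacklevel=2)
        with open(path, "w") as fh:
            if format == "json":
                fh.write("[]\n")
        return
    header = list(rows[0].keys())
    if not header:
        raise ValueError("report rows must have a non-empty header")
    first = header[0]
    ordered = sorted(rows, key=lambda r: (str(r[first])))

    def render(v):
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return f"{v:.{float_dp}f}"
        return str(v)

    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("\t".join(header) + "\n")
            for row in ordered:
                fh.write("\t".join(render(row[h]) for h in header) + "\n")
        else:
            out = [{h: (render(r[h]) if isinstance(r[h], float) else r[h])
                    for h in header} for r in ordered]
            fh.write(json.dumps(out, indent=2) + "\n")
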
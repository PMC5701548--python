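"""Synthetic transcriptome generator with known ground truth.

Emulates the structure the curation pipeline assumes downstream of a
multi-k-mer de novo assembly of pooled samples: a genome with
non-overlapping multi-exon genes, per-gene isoforms generated by
internal-exon skipping, several mutated copies of every transcript
(SNP/indel jitter standing in for the redundant output of different
k-mer runs over genetically variable pooled RNA), occasional
fragmentation of a transcript into two non-overlapping pieces,
micro-organism contaminant sequences, and per-caste expression masks.
Alignment-hit and taxon tables are derived from the ground truth, so
the evidence stage can be exercised without an external aligner.

A single seeded RNG stream drives everything; identical parameters and
seed give byte-identical outputs.  Draw order: per gene (structure,
then isoform chains, then caste mask, then per caste/isoform/copy
mutations), then contaminants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .seqio import AlignmentHit, Contig, write_blast_tab, write_fasta
from .unigene import GeneModel, write_gene_models

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Generator settings; ranges are inclusive (lo, hi) tuples."""

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (100, 200)
    intron_len: tuple[int, int] = (60, 150)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    redundancy_multiplicity: tuple[int, int] = (2, 4)
    snp_rate: float = 0.01
    indel_rate: float = 0.002
    fragmentation: float = 0.1
    n_contaminants: int = 20
    contaminant_len: tuple[int, int] = (300, 800)
    caste_labels: tuple[str, ...] = ("male", "queen", "worker")
    caste_dropout: float = 0.1
    spacer_len: tuple[int, int] = (200, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "fragmentation", "caste_dropout"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "isoforms_per_gene", "redundancy_multiplicity",
                     "contaminant_len", "spacer_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or < 1")
        if not self.caste_labels:
            raise ValueError("at least one caste label is required")


@dataclass
class ContigTruth:
    gene_id: str | None
    chain: tuple[int, ...]
    caste: str
    is_contaminant: bool


@dataclass
class GeneTruth:
    gene_id: str
    chains: list[tuple[int, ...]]
    caste_set: frozenset[str]
    n_exons: int

    @property
    def n_isoforms(self) -> int:
        return len(self.chains)


@dataclass
class TruthTable:
    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)


@dataclass
class SimOutput:
    genome: dict[str, str]
    models: list[GeneModel]
    contigs_by_caste: dict[str, list[Contig]]
    hits: list[AlignmentHit]
    taxa: dict[str, str]
    truth: TruthTable

    def all_contigs(self) -> list[Contig]:
        return [c for caste in sorted(self.contigs_by_caste)
                for c in self.contigs_by_caste[caste]]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _rint(rng: np.random.Generator, rng_tuple: tuple[int, int]) -> int:
    lo, hi = rng_tuple
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(params: SimParams, seed: int | None = None
                       ) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a genome with non-overlapping gene models.

    Genes are separated by random spacers of at least 200 bp; the genome
    is a single sequence ``chr1``.  Deterministic for a fixed seed.
    """
    if params.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pieces: list[str] = []
    models: list[GeneModel] = []
    pos = 0
    for g in range(params.n_genes):
        spacer = _random_seq(rng, _rint(rng, params.spacer_len))
        pieces.append(spacer)
        pos += len(spacer)
        n_exons = _rint(rng, params.exons_per_gene)
        exons: list[tuple[int, int]] = []
        for e in range(n_exons):
            if e > 0:
                intron = _random_seq(rng, _rint(rng, params.intron_len))
                pieces.append(intron)
                pos += len(intron)
            exon = _random_seq(rng, _rint(rng, params.exon_len))
            pieces.append(exon)
            exons.append((pos, pos + len(exon)))
            pos += len(exon)
        models.append(GeneModel(f"g{g:04d}", "chr1", "+", exons))
    pieces.append(_random_seq(rng, _rint(rng, params.spacer_len)))
    return {"chr1": "".join(pieces)}, models


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------

def _mutate(seq: str, snp_rate: float, indel_rate: float,
            rng: np.random.Generator) -> tuple[str, int]:
    """Apply per-base SNP and single-base indel jitter; returns the
    mutated sequence and the number of mutation events."""
    if snp_rate == 0 and indel_rate == 0:
        return seq, 0
    out: list[str] = []
    events = 0
    for ch in seq:
        r = rng.random()
        if r < snp_rate:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[int(rng.integers(0, 3))])
            events += 1
        elif r < snp_rate + indel_rate:
            events += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(ch)
            out.append(str(_BASES[int(rng.integers(0, 4))]))
        else:
            out.append(ch)
    mut = "".join(out)
    return (mut, events) if mut else (seq[:1], events)


def _sample_chains(n_exons: int, n_iso: int, rng: np.random.Generator
                   ) -> list[tuple[int, ...]]:
    """Distinct exon chains by internal-exon skipping.  Every chain keeps
    the first and last exon, so distinct chains always conflict and the
    per-gene isoform count is recoverable exactly on clean data."""
    internal = list(range(1, n_exons - 1))
    all_subsets = [frozenset(c) for r in range(len(internal) + 1)
                   for c in combinations(internal, r)]
    n_iso = min(n_iso, len(all_subsets))
    # always express the full-length form; sample the rest without replacement
    rest = [s for s in all_subsets if s != frozenset(internal)]
    picks = [frozenset(internal)]
    if n_iso > 1:
        idx = rng.choice(len(rest), size=n_iso - 1, replace=False)
        picks += [rest[int(i)] for i in idx]
    chains = []
    for kept_internal in picks:
        chain = tuple([0] + sorted(kept_internal) + ([n_exons - 1]
                                                     if n_exons > 1 else []))
        chains.append(tuple(dict.fromkeys(chain)))
    return sorted(set(chains), key=lambda c: (-len(c), c))


def simulate_contigs(genome: dict[str, str], models: list[GeneModel],
                     params: SimParams, seed: int | None = None) -> SimOutput:
    """Emit per-caste contig sets with truth, hit and taxon tables."""
    rng = np.random.default_rng(
        (params.seed if seed is None else seed) + 1)
    truth = TruthTable()
    contigs_by_caste: dict[str, list[Contig]] = {c: []
                                                 for c in params.caste_labels}
    hits: list[AlignmentHit] = []
    taxa: dict[str, str] = {}
    chrom = genome["chr1"]
    for model in models:
        gid = model.gene_id
        taxa[f"{gid}_p"] = "ant"
        n_iso = _rint(rng, params.isoforms_per_gene)
        chains = _sample_chains(len(model.exons), n_iso, rng)
        # caste mask (redrawn until the gene is expressed somewhere)
        while True:
            mask = [rng.random() >= params.caste_dropout
                    for _ in params.caste_labels]
            if any(mask):
                break
        caste_set = frozenset(c for c, m in zip(params.caste_labels, mask) if m)
        truth.genes[gid] = GeneTruth(gid, chains, caste_set, len(model.exons))
        for caste in params.caste_labels:
            if caste not in caste_set:
                continue
            for iso_idx, chain in enumerate(chains):
                transcript = "".join(chrom[model.exons[i][0]:model.exons[i][1]]
                                     for i in chain)
                n_copies = _rint(rng, params.redundancy_multiplicity)
                for copy in range(n_copies):
                    base_id = f"{caste}_{gid}_i{iso_idx}_c{copy}"
                    fragment = (len(chain) >= 2
                                and rng.random() < params.fragmentation)
                    if fragment:
                        split = int(rng.integers(1, len(chain)))
                        parts = [(chain[:split], "fa"), (chain[split:], "fb")]
                    else:
                        parts = [(chain, "")]
                    for sub_chain, tag in parts:
                        seq = "".join(
                            chrom[model.exons[i][0]:model.exons[i][1]]
                            for i in sub_chain)
                        mut, events = _mutate(seq, params.snp_rate,
                                              params.indel_rate, rng)
                        cid = base_id + (f"_{tag}" if tag else "")
                        contigs_by_caste[caste].append(
                            Contig(id=cid, seq=mut, source=caste))
                        truth.contigs[cid] = ContigTruth(gid, sub_chain,
                                                         caste, False)
                        ident = max(50.0, 100.0 * (1 - events / len(seq)))
                        aa = max(1, len(mut) // 3)
                        hits.append(AlignmentHit(
                            cid, f"{gid}_p", round(ident, 2), aa,
                            int(events), 0, 1, len(mut), 1, aa,
                            1e-30, 2.0 * aa))
    for i in range(params.n_contaminants):
        subject = f"microbe_{i:03d}"
        taxa[subject] = "microorganism"
        seq = _random_seq(rng, _rint(rng, params.contaminant_len))
        caste = params.caste_labels[int(rng.integers(0, len(params.caste_labels)))]
        cid = f"cont_{i:03d}"
        contigs_by_caste[caste].append(Contig(id=cid, seq=seq, source=caste))
        truth.contigs[cid] = ContigTruth(None, (), caste, True)
        aa = max(1, len(seq) // 3)
        hits.append(AlignmentHit(cid, subject, 95.0, aa, 0, 0, 1, len(seq),
                                 1, aa, 1e-20, 2.0 * aa))
    return SimOutput(genome, models, contigs_by_caste, hits, taxa, truth)


def simulate(params: SimParams) -> SimOutput:
    """Reference and contigs in one call, driven by ``params.seed``."""
    genome, models = simulate_reference(params)
    return simulate_contigs(genome, models, params)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_sim(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fasta, models.gff3, contigs_<caste>.fasta, hits.tsv,
    taxa.tsv and truth tables; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fasta"
    write_fasta([Contig(id=t, seq=s) for t, s in sorted(sim.genome.items())],
                paths["genome"])
    paths["models"] = outdir / "models.gff3"
    write_gene_models(sim.models, paths["models"])
    for caste in sorted(sim.contigs_by_caste):
        p = outdir / f"contigs_{caste}.fasta"
        write_fasta(sim.contigs_by_caste[caste], p)
        paths[f"contigs_{caste}"] = p
    paths["hits"] = outdir / "hits.tsv"
    write_blast_tab(sim.hits, paths["hits"])
    paths["taxa"] = outdir / "taxa.tsv"
    with open(paths["taxa"], "w") as fh:
        fh.write("subject_id\ttaxon_class\n")
        for sid in sorted(sim.taxa):
            fh.write(f"{sid}\t{sim.taxa[sid]}\n")
    paths["truth_contigs"] = outdir / "truth_contigs.tsv"
    with open(paths["truth_contigs"], "w") as fh:
        fh.write("contig_id\tgene_id\tchain\tcaste\tis_contaminant\n")
        for cid in sorted(sim.truth.contigs):
            t = sim.truth.contigs[cid]
            chain = ",".join(map(str, t.chain))
            fh.write(f"{cid}\t{t.gene_id or '.'}\t{chain or '.'}\t{t.caste}"
                     f"\t{int(t.is_contaminant)}\n")
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    with open(paths["truth_genes"], "w") as fh:
        fh.write("gene_id\tn_isoforms\tn_exons\tcastes\tchains\n")
        for gid in sorted(sim.truth.genes):
            g = sim.truth.genes[gid]
            chains = ";".join(",".join(map(str, c)) for c in g.chains)
            fh.write(f"{gid}\t{g.n_isoforms}\t{g.n_exons}"
                     f"\t{','.join(sorted(g.caste_set))}\t{chains}\n")
    return paths


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(result, truth: TruthTable) -> dict:
    """Score pipeline outputs against the ground truth.

    ``result`` is a pipeline result object exposing ``cluster_map``,
    ``partition``, ``consensus_genes`` and ``presence``.  Reported
    metrics: gene-count recovery, per-gene isoform-count exact-match
    rate, contaminant classification precision/recall (absent when the
    truth has no contaminants), and a caste-unique exact-match flag.
    """
    known = set(truth.contigs)
    for rep in result.cluster_map.members:
        for m in result.cluster_map.members[rep]:
            if m not in known:
                raise ValueError(f"pipeline contig {m!r} absent from truth")
    true_genes = set(truth.genes)
    found = {g for g, cg in result.consensus_genes.items() if cg.assigned}
    gene_recovery = len(found & true_genes) / len(true_genes)
    iso_exact = sum(
        1 for gid in true_genes
        if gid in result.consensus_genes
        and result.consensus_genes[gid].n_isoforms == truth.genes[gid].n_isoforms
    ) / len(true_genes)
    true_cont = {cid for cid, t in truth.contigs.items() if t.is_contaminant}
    pred_cont = {m for rep in result.partition.ids_in("microorganism")
                 for m in result.cluster_map.members.get(rep, [rep])}
    if true_cont:
        precision = (len(pred_cont & true_cont) / len(pred_cont)
                     if pred_cont else 0.0)
        recall = len(pred_cont & true_cont) / len(true_cont)
    else:
        precision = recall = None
    caste_exact = None
    if result.presence is not None:
        from .castego import venn_partition
        venn = venn_partition(result.presence)
        castes = result.presence.castes
        true_unique = {c: {gid for gid, g in truth.genes.items()
                           if g.caste_set == frozenset([c])} for c in castes}
        caste_exact = all(venn.unique[c] == true_unique[c] for c in castes)
    return {
        "gene_count_recovery": gene_recovery,
        "isoform_exact_match_rate": iso_exact,
        "contaminant_precision": precision,
        "contaminant_recall": recall,
        "caste_unique_exact": caste_exact,
        "n_true_genes": len(true_genes),
        "n_found_genes": len(found),
    }
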
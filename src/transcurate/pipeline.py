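"""End-to-end curation pipeline.

Wires the stages in their published order — redundancy collapse of the
pooled assemblies, the 200 bp annotation length floor, evidence-based
classification, spliced-alignment grouping of isoforms into reference
genes with unigene selection, and the caste presence partition — and
writes every intermediate plus a run manifest.  Reruns on identical
inputs and configuration reproduce identical outputs (manifest
timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .castego import CasteMatrix, venn_partition
from .collapse import ClusterMap, collapse_contigs
from .config import PipelineConfig
from .evidence import (EvidencePartition, classify_contigs, length_filter,
                       partition_report)
from .metrics import assembly_stats
from .seqio import (AlignmentHit, Contig, SplicedAlignment, read_blast_tab,
                    read_fasta, read_spliced_gff3, read_taxa, write_fasta,
                    write_report, write_spliced_gff3)
from .simulate import SimOutput
from .unigene import (ConsensusGene, GeneModel, GenomeIndex, group_genes,
                      isoform_summary, read_gene_models, select_unigenes,
                      splice_map)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    source_of: dict[str, str]
    meta_contigs: list[Contig]
    cluster_map: ClusterMap
    kept: list[Contig]
    dropped_short: list[Contig]
    partition: EvidencePartition
    alignments: list[SplicedAlignment]
    consensus_genes: dict[str, ConsensusGene]
    unplaced: list[str]
    unigenes: list[Contig]
    presence: CasteMatrix | None
    manifest: dict = field(default_factory=dict)


def _check_conservation(n_input: int, cmap: ClusterMap,
                        kept: list[Contig], dropped: list[Contig]) -> None:
    """Every input contig must be accounted for in exactly one of
    {collapsed-away, short-dropped, classified}."""
    n_members = sum(len(m) for m in cmap.members.values())
    n_reps = len(cmap.members)
    if n_members != n_input:
        raise RuntimeError(f"collapse stage lost contigs: "
                           f"{n_members} members != {n_input} inputs")
    if len(kept) + len(dropped) != n_reps:
        raise RuntimeError("length filter lost contigs")


def curate(contigs: list[Contig], hits: list[AlignmentHit],
           taxa: dict[str, str], genome: dict[str, str] | None = None,
           models: list[GeneModel] | None = None,
           alignments: list[SplicedAlignment] | None = None,
           config: PipelineConfig | None = None) -> PipelineResult:
    """Run the curation stages in memory.

    Spliced alignments are taken from ``alignments`` when given (real
    aligner output); otherwise the internal k-mer mapper aligns the
    evidence contigs against ``genome``.
    """
    cfg = config or PipelineConfig()
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique across assemblies "
                         "(prefix them with their source label)")
    source_of = {c.id: c.source for c in contigs}
    logger.info("collapse: %d contigs in, min_overlap=%d min_identity=%.1f",
                len(contigs), cfg.merge_min_overlap, cfg.merge_min_identity)
    meta, cmap = collapse_contigs(contigs, cfg.merge_min_overlap,
                                  cfg.merge_min_identity)
    logger.info("collapse: %d non-redundant contigs", len(meta))
    kept, dropped = length_filter(meta, cfg.min_contig_len_annot)
    _check_conservation(len(contigs), cmap, kept, dropped)
    kept_ids = {c.id for c in kept}
    usable_hits = [h for h in hits if h.query_id in kept_ids]
    partition = classify_contigs(kept, usable_hits, taxa, cfg,
                                 dropped_short=[c.id for c in dropped])
    counts = partition.counts()
    logger.info("evidence: %s over %d length-passing contigs",
                counts, len(kept))
    evidence_ids = partition.ids_in("ant") | partition.ids_in("other_insect")
    by_id = {c.id: c for c in contigs}
    if alignments is not None:
        alns = [a for a in alignments if a.contig_id in evidence_ids]
    elif genome is not None:
        index = GenomeIndex(genome)
        alns = []
        for cid in sorted(evidence_ids):
            aln = splice_map(by_id[cid], index)
            if aln is not None:
                alns.append(aln)
    else:
        alns = []
    consensus: dict[str, ConsensusGene] = {}
    unplaced: list[str] = []
    unigenes: list[Contig] = []
    if models and alns:
        consensus, unplaced = group_genes(alns, models,
                                          tol=cfg.isoform_boundary_tol)
        unigenes = select_unigenes(consensus, by_id)
        logger.info("unigene: %d genes, %d unigenes, %d unplaced contigs",
                    len(consensus), len(unigenes), len(unplaced))
    presence = None
    sources = {s for s in source_of.values() if s}
    if consensus and len(sources) >= 1:
        caste_genes: dict[str, set[str]] = {s: set() for s in sorted(sources)}
        for gid, gene in consensus.items():
            for cid in gene.assigned:
                for member in cmap.members.get(cid, [cid]):
                    src = source_of.get(member, "")
                    if src:
                        caste_genes[src].add(gid)
        if any(caste_genes.values()):
            presence = CasteMatrix.from_sets(caste_genes)
    return PipelineResult(
        config=cfg, source_of=source_of, meta_contigs=meta, cluster_map=cmap,
        kept=kept, dropped_short=dropped, partition=partition,
        alignments=alns, consensus_genes=consensus, unplaced=unplaced,
        unigenes=unigenes, presence=presence)


def curate_sim(sim: SimOutput, config: PipelineConfig | None = None
               ) -> PipelineResult:
    """Convenience: run :func:`curate` on a simulator output."""
    return curate(sim.all_contigs(), sim.hits, sim.taxa,
                  genome=sim.genome, models=sim.models, config=config)


# ---------------------------------------------------------------------------
# file-based runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    contig_fastas: dict[str, Path]        # source label -> path
    hits: Path
    taxa: Path
    genome: Path | None = None
    models: Path | None = None
    alignments: Path | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs,
                 outdir: str | Path) -> PipelineResult:
    """Read inputs, run :func:`curate`, serialize every stage and emit a
    run manifest (``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    contigs: list[Contig] = []
    for source in sorted(inputs.contig_fastas):
        contigs.extend(read_fasta(inputs.contig_fastas[source], source=source))
    hits = read_blast_tab(inputs.hits)
    if not inputs.taxa or not Path(inputs.taxa).exists():
        raise FileNotFoundError(
            "evidence stage requires a taxon table (subject_id -> taxon "
            f"class); missing: {inputs.taxa}")
    taxa = read_taxa(inputs.taxa)
    genome = None
    if inputs.genome:
        genome = {c.id: c.seq for c in read_fasta(inputs.genome)}
    models = read_gene_models(inputs.models) if inputs.models else None
    alignments = (read_spliced_gff3(inputs.alignments)
                  if inputs.alignments else None)
    result = curate(contigs, hits, taxa, genome=genome, models=models,
                    alignments=alignments, config=config)
    # --- serialize stages ----------------------------------------------
    write_fasta(result.meta_contigs, outdir / "meta_contigs.fasta")
    write_report([{"member_id": m, "representative_id": rep}
                  for rep in sorted(result.cluster_map.members)
                  for m in result.cluster_map.members[rep]],
                 outdir / "clusters.tsv")
    write_report([{"contig_id": cid, "class": cls}
                  for cid, cls in sorted(result.partition.class_of.items())],
                 outdir / "partition.tsv")
    write_report(partition_report(result.partition),
                 outdir / "evidence_report.tsv", float_dp=1)
    if result.alignments:
        write_spliced_gff3(result.alignments, outdir / "alignments.gff3")
    if result.consensus_genes:
        write_fasta(result.unigenes, outdir / "unigenes.fasta")
        iso_rows = []
        for gid in sorted(result.consensus_genes):
            gene = result.consensus_genes[gid]
            for gi, group in enumerate(gene.isoform_groups):
                for cid in group:
                    iso_rows.append({
                        "gene_id": gid, "isoform_group": gi, "contig_id": cid,
                        "chain": ",".join(map(str, gene.assigned[cid])),
                        "is_representative": cid == gene.representative_id})
        write_report(iso_rows, outdir / "isoforms.tsv")
        summ = isoform_summary(result.consensus_genes)
        write_report([dataclasses.asdict(summ) | {"name": "isoforms"}],
                     outdir / "isoform_summary.json", format="json")
    if result.presence is not None:
        venn = venn_partition(result.presence)
        write_report([{"region": "+".join(sorted(k)), "n_genes": len(v)}
                      for k, v in venn.regions.items()],
                     outdir / "caste_venn.tsv")
    # --- manifest ------------------------------------------------------
    stats = assembly_stats(result.meta_contigs)
    counts = result.partition.counts()
    manifest = {
        "tool": "transcurate",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in
                   [*inputs.contig_fastas.values(), inputs.hits, inputs.taxa,
                    inputs.genome, inputs.models, inputs.alignments] if p},
        "stage_counts": {
            "input_contigs": len(contigs),
            "meta_contigs": len(result.meta_contigs),
            "meta_n50": stats.n50,
            "short_dropped": len(result.dropped_short),
            "length_passing": len(result.kept),
            **{f"class_{k}": v for k, v in counts.items()},
            "genes": len(result.consensus_genes),
            "unigenes": len(result.unigenes),
            "unplaced_contigs": len(result.unplaced),
        },
        "timestamps": {"started": started,
                       "finished": datetime.now(timezone.utc).isoformat()},
    }
    if sum(counts.values()) != len(result.kept):
        raise RuntimeError("evidence classes do not sum to length-passing "
                           "contigs")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.manifest = manifest
    return result
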
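"""Pipeline configuration.

Every numeric threshold used by the curation stages lives here, with
defaults matching the published pipeline: a 100 bp floor on assembled
contigs, a 200 bp floor before annotation, collapse of contigs that
overlap by >=100 bases at >=95% identity, reference-protein
deduplication at >=90% identity over >=90% of the shorter sequence,
evidence filtering at >=70% amino-acid identity over >=33 aligned
residues (100 bases) with e-value <=1e-3, and an assembly-evaluation
screen at >=50% identity over >=50 residues.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Numeric thresholds for every curation stage.

    All identities are percentages in [0, 100]; lengths are base pairs
    unless the field name says amino acids (``_aa``); fractions are in
    [0, 1].
    """

    min_contig_len_initial: int = 100
    min_contig_len_annot: int = 200
    merge_min_overlap: int = 100
    merge_min_identity: float = 95.0
    protdedup_min_identity: float = 90.0
    protdedup_min_overlap_frac: float = 0.90
    evidence_min_identity: float = 70.0
    evidence_min_aln_aa: int = 33
    evidence_min_aln_nt: int = 100
    evidence_max_evalue: float = 1e-3
    coverage_high_bin: float = 0.90
    compare_min_identity: float = 50.0
    compare_min_aln_aa: int = 50
    isoform_boundary_tol: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("merge_min_identity", "protdedup_min_identity",
                     "evidence_min_identity", "compare_min_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        for name in ("protdedup_min_overlap_frac", "coverage_high_bin"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be a fraction in (0, 1], got {v}")
        for name in ("min_contig_len_initial", "min_contig_len_annot",
                     "merge_min_overlap", "evidence_min_aln_aa",
                     "evidence_min_aln_nt", "compare_min_aln_aa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.evidence_max_evalue < 0:
            raise ValueError("evidence_max_evalue must be non-negative")
        if self.isoform_boundary_tol < 0:
            raise ValueError("isoform_boundary_tol must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
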
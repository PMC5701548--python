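"""Caste-specific gene partitions and GO-term frequency comparison.

Social-insect castes (queen, worker, male) share one genome, so which
genes are *detected* in each caste's assembly is itself informative.
Given a gene-by-caste presence matrix this module enumerates every Venn
region (genes unique to one caste, shared by the two female castes,
shared by all, ...).  It also compares gene-ontology term frequency
profiles between two gene sets — e.g. a unigene set with isoforms
counted versus one isoform per gene — with a paired t-test across the GO
terms shared by the two profiles, per GO category.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

GO_CATEGORIES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class CasteMatrix:
    """Boolean gene x caste presence table."""

    table: pd.DataFrame  # index: gene ids; columns: caste labels; bool

    def __post_init__(self) -> None:
        if self.table.shape[1] < 1:
            raise ValueError("CasteMatrix needs at least one caste")
        self.table = self.table.astype(bool)
        absent = self.table.index[~self.table.any(axis=1)]
        if len(absent):
            raise ValueError(f"genes present in no caste: "
                             f"{sorted(absent.tolist())[:5]} ...")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene ids in CasteMatrix")

    @classmethod
    def from_sets(cls, caste_genes: dict[str, set[str]]) -> "CasteMatrix":
        genes = sorted(set().union(*caste_genes.values()))
        data = {caste: [g in gs for g in genes]
                for caste, gs in caste_genes.items()}
        return cls(pd.DataFrame(data, index=genes))

    @property
    def castes(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class VennPartition:
    regions: dict[frozenset[str], set[str]]
    unique: dict[str, set[str]]
    shared_all: set[str]
    female_only: set[str] | None


def venn_partition(matrix: CasteMatrix) -> VennPartition:
    """All 2^k - 1 presence regions of the caste Venn diagram.

    Regions are disjoint and exhaustive.  Derived aggregates: the genes
    unique to each caste, the genes shared by all castes, and — when
    queen, worker and male columns all exist — the female-only set
    (queen and worker but not male).
    """
    castes = matrix.castes
    if len(castes) > 6:
        raise ValueError("venn_partition supports at most 6 castes")
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(castes) + 1):
        for combo in combinations(castes, r):
            regions[frozenset(combo)] = set()
    for gene, row in matrix.table.iterrows():
        present = frozenset(c for c in castes if row[c])
        regions[present].add(gene)
    unique = {c: regions[frozenset([c])] for c in castes}
    shared_all = regions[frozenset(castes)]
    female_only = None
    if {"queen", "worker", "male"} <= set(castes):
        female_only = {g for key, gs in regions.items() for g in gs
                       if {"queen", "worker"} <= key and "male" not in key}
    return VennPartition(regions, unique, shared_all, female_only)


# ---------------------------------------------------------------------------
# GO term frequencies
# ---------------------------------------------------------------------------

def go_frequency(annotations: pd.DataFrame, gene_set: set[str] | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Per-category GO term gene counts and percentages.

    ``annotations`` must have columns gene_id, go_id, category.  A gene
    contributes to every term it carries, so percentages are of the
    category's summed gene counts, not of the gene total.
    """
    required = {"gene_id", "go_id", "category"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    df = annotations.drop_duplicates(["gene_id", "go_id", "category"])
    if gene_set is not None:
        df = df[df.gene_id.isin(gene_set)]
        if df.empty:
            raise ValueError("no annotated genes in the given gene set")
    tables: dict[str, pd.DataFrame] = {}
    for category, sub in df.groupby("category"):
        counts = (sub.groupby("go_id").gene_id.nunique()
                  .rename("gene_count").sort_index().reset_index())
        counts["percent"] = 100.0 * counts.gene_count / counts.gene_count.sum()
        tables[category] = counts
    return tables


@dataclass
class GOComparison:
    category: str
    t: float
    df: int
    p: float
    n_terms: int


def compare_go(a: dict[str, pd.DataFrame], b: dict[str, pd.DataFrame],
               paired: bool = True) -> dict[str, GOComparison]:
    """Compare two GO frequency profiles per category.

    Default is a paired t-test over the per-term percentage differences
    restricted to terms present in both tables (df = shared terms - 1);
    ``paired=False`` runs Welch's unequal-variance two-sample test
    instead.  Identical profiles give t = 0, p = 1.
    """
    out: dict[str, GOComparison] = {}
    for category in sorted(set(a) & set(b)):
        ta = a[category].set_index("go_id").percent
        tb = b[category].set_index("go_id").percent
        shared = sorted(set(ta.index) & set(tb.index))
        if len(shared) < 2:
            raise ValueError(f"category {category!r}: fewer than 2 shared "
                             f"GO terms")
        x, y = ta.loc[shared].to_numpy(), tb.loc[shared].to_numpy()
        if paired:
            if (x == y).all():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(x, y)
            df = len(shared) - 1
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            df = len(shared) - 1  # reported term count basis
        out[category] = GOComparison(category, float(t), df, float(p),
                                     len(shared))
    return out
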
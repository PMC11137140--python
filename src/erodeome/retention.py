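"""Retention matrix assembly, genome-feature summaries and pathway logic.

Collects per-lineage gene calls into a genes x lineages status matrix,
derives the binary retention matrix (intact -> 1, pseudogene/missing -> 0),
categorises genes as universally intact, universally lost or fractionally
retained, computes per-lineage genome features (GC of conserved orthologs,
fraction of the reference recovered, status counts, per-category retention),
evaluates biosynthetic-pathway completeness with host complementation, and
fits simple feature-vs-divergence trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reference_io import GeneCall, LineageGenome, Reference, PathwayDefinition

__all__ = [
    "RetentionMatrix",
    "GenomeFeatures",
    "build_matrix",
    "genome_features",
    "features_table",
    "pathway_status",
    "feature_trends",
]

_STATUS_CODE = {"intact": "I", "pseudogene": "P", "missing": "M"}
_CODE_STATUS = {v: k for k, v in _STATUS_CODE.items()}

CATEGORIES = ("universal_intact", "universal_lost", "fractional")


@dataclass
class RetentionMatrix:
    """Genes x lineages functional-status matrix.

    ``status`` holds cells in {I, P, M}; ``binary`` collapses to intact (1)
    versus non-intact (0).  Each gene belongs to exactly one category:
    ``universal_intact`` (all 1), ``universal_lost`` (all 0) or
    ``fractional`` otherwise.
    """

    status: pd.DataFrame  # index gene_ids, columns lineage_ids, cells I/P/M

    @property
    def gene_ids(self) -> list:
        return list(self.status.index)

    @property
    def lineage_ids(self) -> list:
        return list(self.status.columns)

    @property
    def n_lineages(self) -> int:
        return self.status.shape[1]

    @property
    def binary(self) -> pd.DataFrame:
        return (self.status == "I").astype(int)

    @property
    def category(self) -> pd.Series:
        b = self.binary
        row = b.sum(axis=1)
        cat = pd.Series("fractional", index=b.index, name="category")
        cat[row == b.shape[1]] = "universal_intact"
        cat[row == 0] = "universal_lost"
        return cat

    def fractional(self) -> "RetentionMatrix":
        keep = self.category == "fractional"
        return RetentionMatrix(self.status.loc[keep])

    def category_counts(self) -> dict:
        c = self.category.value_counts()
        return {k: int(c.get(k, 0)) for k in CATEGORIES}

    def to_tsv(self, path) -> None:
        self.status.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "RetentionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index.name = None
        df.columns.name = None
        bad = set(np.unique(df.to_numpy())) - set("IPM")
        if bad:
            raise ValueError(f"{path}: invalid status codes {sorted(bad)}")
        return cls(df)


def build_matrix(calls, exclusions=(), gene_order=None) -> RetentionMatrix:
    """Assemble gene calls into a retention matrix.

    ``exclusions`` names lineages dropped before categorisation (the study's
    declarative analogue of removing conspecific / recently-cospeciated
    samples).  Every (gene, lineage) pair must occur exactly once; lineage
    order is canonicalised (sorted), so input order is irrelevant.
    """
    cells = {}
    genes_seen, lineages_seen = [], []
    dup = []
    for c in calls:
        key = (c.gene_id, c.lineage_id)
        if key in cells:
            dup.append(key)
        cells[key] = _STATUS_CODE[c.status]
    if dup:
        raise ValueError(f"duplicate (gene, lineage) pairs: {sorted(set(dup))[:10]}")
    gene_ids = sorted({g for g, _ in cells}) if gene_order is None else list(gene_order)
    lineage_ids = sorted({l for _, l in cells})
    unknown = set(exclusions) - set(lineage_ids)
    if unknown:
        raise ValueError(f"exclusion list names unknown lineages: {sorted(unknown)}")
    lineage_ids = [l for l in lineage_ids if l not in set(exclusions)]
    missing = [
        (g, l) for g in gene_ids for l in lineage_ids if (g, l) not in cells
    ]
    if missing:
        raise ValueError(f"missing (gene, lineage) pairs: {missing[:10]}")
    data = [[cells[(g, l)] for l in lineage_ids] for g in gene_ids]
    return RetentionMatrix(
        pd.DataFrame(data, index=gene_ids, columns=lineage_ids, dtype=str)
    )


# ---------------------------------------------------------------------------
# genome features
# ---------------------------------------------------------------------------

@dataclass
class GenomeFeatures:
    """Per-lineage summary of genome state."""

    lineage_id: str
    gc_conserved_orthologs: float
    fraction_reference_recovered: float
    n_intact: int
    n_pseudo: int
    n_missing: int
    category_counts: dict = field(default_factory=dict)  # functional tag -> intact count


def _gene_consensus(lineage, gene):
    from .reference_io import revcomp

    body = lineage.consensus[gene.replicon_id][gene.start : gene.end]
    if gene.strand == "-":
        body = revcomp(body)
    return body


def genome_features(lineage_calls, reference: Reference,
                    lineage: LineageGenome, conserved_set=None) -> GenomeFeatures:
    """Summarise one lineage.

    GC is pooled over the consensus of *intact* copies of the conserved
    ortholog set (defaults to all genes called intact in this lineage when no
    set is supplied); recovery is the non-gap, non-N fraction of the whole
    consensus relative to the reference length.
    """
    calls = list(lineage_calls)
    by_gene = {c.gene_id: c for c in calls}
    if conserved_set is None:
        conserved_set = {c.gene_id for c in calls if c.status == "intact"}
    gc = total = 0
    for gid in sorted(conserved_set):
        call = by_gene.get(gid)
        if call is None or call.status != "intact":
            continue
        seq = _gene_consensus(lineage, reference.gene(gid))
        for ch in seq:
            if ch in "GC":
                gc += 1
            if ch in "ACGT":
                total += 1
    recovered = sum(
        sum(1 for ch in seq if ch not in "-N") for seq in lineage.consensus.values()
    )
    counts = {"intact": 0, "pseudogene": 0, "missing": 0}
    for c in calls:
        counts[c.status] += 1
    cat_counts = {}
    for g in reference.genes:
        call = by_gene.get(g.gene_id)
        for tag in g.categories:
            cat_counts.setdefault(tag, 0)
            if call is not None and call.status == "intact":
                cat_counts[tag] += 1
    return GenomeFeatures(
        lineage_id=lineage.lineage_id,
        gc_conserved_orthologs=gc / total if total else float("nan"),
        fraction_reference_recovered=recovered / reference.total_length,
        n_intact=counts["intact"], n_pseudo=counts["pseudogene"],
        n_missing=counts["missing"], category_counts=cat_counts,
    )


def features_table(features) -> pd.DataFrame:
    """Stack GenomeFeatures rows into a lineage-indexed DataFrame."""
    rows = []
    for f in features:
        row = {
            "lineage_id": f.lineage_id,
            "gc_conserved_orthologs": f.gc_conserved_orthologs,
            "fraction_reference_recovered": f.fraction_reference_recovered,
            "n_intact": f.n_intact, "n_pseudo": f.n_pseudo,
            "n_missing": f.n_missing,
        }
        for tag, n in f.category_counts.items():
            row[f"n_intact_{tag}"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("lineage_id")


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def pathway_status(pathway: PathwayDefinition, lineage_calls) -> tuple:
    """Pathway completeness for one lineage.

    A step is satisfied if any of its alternative genes is intact, or if any
    of them is host-complemented; the pathway is intact only when every step
    is satisfied.  Returns ``(status, details)`` where details is a list of
    ``(step_id, satisfied, how)``.
    """
    status_by_gene = {
        c.gene_id: c.status for c in lineage_calls
    } if not isinstance(lineage_calls, dict) else lineage_calls
    details = []
    ok = True
    for step_id, alts in pathway.required_steps:
        how = None
        for g in sorted(alts):
            if status_by_gene.get(g) == "intact":
                how = f"intact:{g}"
                break
        if how is None:
            for g in sorted(alts):
                if g in pathway.host_complemented:
                    how = f"host:{g}"
                    break
        satisfied = how is not None
        ok &= satisfied
        details.append((step_id, satisfied, how or "unsatisfied"))
    return ("intact" if ok else "broken"), details


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------

def feature_trends(features: pd.DataFrame, distances) -> pd.DataFrame:
    """OLS slope, R^2 and Spearman rank correlation of each feature against
    patristic distance.  Constant features get slope 0, R^2 0, rho NaN."""
    d = pd.Series(distances)
    d = d.reindex(features.index)
    if d.isna().any():
        raise ValueError(f"no distance for lineages {list(d[d.isna()].index)}")
    rows = []
    for col in features.columns:
        y = features[col].astype(float)
        if np.ptp(y.to_numpy()) == 0:
            rows.append({"feature": col, "slope": 0.0, "r2": 0.0, "spearman_rho": float("nan")})
            continue
        fit = stats.linregress(d.to_numpy(), y.to_numpy())
        rho = stats.spearmanr(d.to_numpy(), y.to_numpy()).statistic
        rows.append({"feature": col, "slope": float(fit.slope),
                     "r2": float(fit.rvalue**2), "spearman_rho": float(rho)})
    return pd.DataFrame(rows).set_index("feature")
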
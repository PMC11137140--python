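"""Shared data model and file I/O for the degeneration pipeline.

Defines the reference gene inventory, per-lineage reference-aligned consensus
genomes, pathway definitions and per-(gene, lineage) calls, together with
readers/writers for FASTA, GFF3, BED-like TSV, gene-call TSV and pathway
JSON/YAML.

Coordinate convention: 0-based, half-open, on the forward strand of the
replicon, everywhere in memory.  GFF3 I/O performs the +/-1 conversion at the
boundary.  CDS sequences are stored in 5'->3' reading direction (minus-strand
genes are reverse-complemented on extraction).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "STOP_CODONS",
    "STATUSES",
    "ReferenceGene",
    "LineageGenome",
    "PathwayDefinition",
    "GeneCall",
    "Reference",
    "revcomp",
    "read_reference",
    "write_reference",
    "read_lineage",
    "read_gene_calls",
    "write_gene_calls",
    "read_pathways",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
STATUSES = ("intact", "pseudogene", "missing")

#: consensus alphabet in reference coordinates; '-' marks a deleted position
CONSENSUS_ALPHABET = frozenset("ACGTN-")


def revcomp(seq: str) -> str:
    """Reverse complement preserving N and '-' characters."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGene:
    """One ancestor protein-coding gene.

    ``start``/``end`` are 0-based half-open on the forward strand of
    ``replicon_id``; ``cds_seq`` is the forward-reading coding sequence,
    beginning with the start codon and ending with the stop codon.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    cds_seq: str
    product: str = ""
    categories: frozenset = frozenset()
    group_ids: frozenset = frozenset()

    def invariant_violations(self) -> list[str]:
        """Return reasons this gene breaks the CDS invariants (empty if valid)."""
        problems = []
        if self.end - self.start != len(self.cds_seq):
            problems.append("length")
        if len(self.cds_seq) % 3 != 0:
            problems.append("frame")
        elif self.cds_seq[-3:] not in STOP_CODONS:
            problems.append("stop")
        if self.strand not in "+-":
            problems.append("strand")
        return problems


@dataclass
class LineageGenome:
    """A reference-aligned consensus genome for one endosymbiont lineage.

    ``consensus`` maps replicon id to a string of exactly the reference
    replicon length over {A,C,G,T,N,-}; '-' marks positions deleted in the
    lineage, so reference coordinates apply unchanged.
    """

    lineage_id: str
    consensus: dict
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PathwayDefinition:
    """Required biosynthetic steps of a pathway, with host complementation.

    Each step maps to the set of alternative genes able to perform it; a step
    is satisfiable by any one of them, or by the host if the gene appears in
    ``host_complemented``.
    """

    pathway_id: str
    required_steps: tuple  # ordered tuple of (step_id, frozenset of gene_ids)
    host_complemented: frozenset = frozenset()

    def validate(self, known_gene_ids: set) -> None:
        if not self.required_steps:
            raise ValueError(f"pathway {self.pathway_id}: no required steps")
        for step_id, alts in self.required_steps:
            unknown = set(alts) - known_gene_ids
            if unknown:
                raise ValueError(
                    f"pathway {self.pathway_id} step {step_id}: "
                    f"unknown gene ids {sorted(unknown)}"
                )


@dataclass
class GeneCall:
    """Functional status of one reference gene in one lineage."""

    gene_id: str
    lineage_id: str
    status: str
    snled: float
    coverage: float
    best_candidate: object | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"invalid status {self.status!r}")


@dataclass
class Reference:
    """Replicon sequences plus the validated gene inventory."""

    replicons: dict  # replicon_id -> sequence (str, uppercase)
    genes: list  # list[ReferenceGene]

    @property
    def gene_ids(self) -> list:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> ReferenceGene:
        try:
            return self._index[gene_id]
        except AttributeError:
            self._index = {g.gene_id: g for g in self.genes}
            return self._index[gene_id]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.replicons.values())


# ---------------------------------------------------------------------------
# reference reading
# ---------------------------------------------------------------------------

def _read_fasta(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def _parse_gff3(path) -> list:
    """Yield (replicon, start0, end, strand, gene_id, product, categories, groups)
    for every CDS feature, converting 1-based closed to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
        if gene_id is None:
            raise ValueError(f"{path}: CDS at {feat.seqid}:{feat.start} lacks ID")
        product = (attrs.get("product") or [""])[0]
        categories = frozenset(attrs.get("category") or [])
        groups = frozenset(attrs.get("group") or [])
        rows.append(
            (feat.seqid, feat.start - 1, feat.end, feat.strand, gene_id,
             product, categories, groups)
        )
    return rows


def _parse_bed_tsv(path) -> list:
    """BED-like TSV: replicon, start, end, strand, gene_id, [product, categories, groups].
    Coordinates are already 0-based half-open."""
    import csv

    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns")
            replicon, start, end, strand, gene_id = row[:5]
            product = row[5] if len(row) > 5 else ""
            categories = frozenset(filter(None, row[6].split(","))) if len(row) > 6 else frozenset()
            groups = frozenset(filter(None, row[7].split(","))) if len(row) > 7 else frozenset()
            rows.append((replicon, int(start), int(end), strand, gene_id,
                         product, categories, groups))
    return rows


def read_reference(fasta_path, annotation_path) -> tuple:
    """Read replicon FASTA plus gene coordinates (GFF3 or BED-like TSV).

    Returns ``(Reference, rejected)`` where ``rejected`` is a list of
    ``(ReferenceGene, reasons)`` for genes that fail the CDS invariants
    (frame, terminal stop codon); such genes are reported, never silently
    dropped.

    Raises on missing files, unknown replicons, out-of-range coordinates and
    duplicate gene ids.
    """
    replicons = _read_fasta(fasta_path)
    annotation_path = Path(annotation_path)
    if not annotation_path.exists():
        raise FileNotFoundError(str(annotation_path))
    if annotation_path.suffix.lower() in {".gff", ".gff3"}:
        rows = _parse_gff3(annotation_path)
    else:
        rows = _parse_bed_tsv(annotation_path)

    genes, rejected, seen = [], [], set()
    for replicon, start, end, strand, gene_id, product, categories, groups in rows:
        if replicon not in replicons:
            raise ValueError(f"gene {gene_id}: replicon {replicon!r} not in FASTA")
        seq = replicons[replicon]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"gene {gene_id}: coordinates [{start},{end}) out of range "
                f"for {replicon} (length {len(seq)})"
            )
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id}")
        seen.add(gene_id)
        cds = seq[start:end]
        if strand == "-":
            cds = revcomp(cds)
        gene = ReferenceGene(
            gene_id=gene_id, replicon_id=replicon, start=start, end=end,
            strand=strand, cds_seq=cds, product=product,
            categories=categories, group_ids=groups,
        )
        problems = gene.invariant_violations()
        if problems:
            rejected.append((gene, problems))
        else:
            genes.append(gene)
    return Reference(replicons=replicons, genes=genes), rejected


def write_reference(reference: Reference, fasta_path, gff3_path) -> None:
    """Write replicons as FASTA and the gene inventory as GFF3 (1-based closed)."""
    with open(fasta_path, "w") as fh:
        for rid, seq in reference.replicons.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, seq in reference.replicons.items():
            fh.write(f"##sequence-region {rid} 1 {len(seq)}\n")
        for g in reference.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.categories:
                attrs.append("category=" + ",".join(sorted(g.categories)))
            if g.group_ids:
                attrs.append("group=" + ",".join(sorted(g.group_ids)))
            fh.write(
                "\t".join(
                    [g.replicon_id, "erodeome", "CDS", str(g.start + 1),
                     str(g.end), ".", g.strand, "0", ";".join(attrs)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# lineage consensus reading
# ---------------------------------------------------------------------------

def read_lineage(fasta_path, reference: Reference, *, lineage_id=None,
                 coerce_ambiguous=False, metadata=None) -> LineageGenome:
    """Read a reference-aligned consensus FASTA for one lineage.

    Every record id must name a reference replicon and its sequence must have
    exactly the reference length (deletions are '-', no insertions).
    Lower-case input is upper-cased; characters outside {A,C,G,T,N,-} raise
    unless ``coerce_ambiguous`` is set, in which case they become N.
    """
    records = _read_fasta(fasta_path)
    consensus = {}
    for rid, seq in records.items():
        if rid not in reference.replicons:
            raise ValueError(f"{fasta_path}: unknown replicon {rid!r}")
        ref_len = len(reference.replicons[rid])
        if len(seq) != ref_len:
            raise ValueError(
                f"{fasta_path}: length mismatch on replicon {rid}: "
                f"consensus {len(seq)} vs reference {ref_len}"
            )
        bad = set(seq) - CONSENSUS_ALPHABET
        if bad:
            if coerce_ambiguous:
                seq = "".join(c if c in CONSENSUS_ALPHABET else "N" for c in seq)
            else:
                raise ValueError(
                    f"{fasta_path}: replicon {rid}: invalid characters {sorted(bad)}"
                )
        consensus[rid] = seq
    missing = set(reference.replicons) - set(consensus)
    if missing:
        raise ValueError(f"{fasta_path}: missing replicons {sorted(missing)}")
    if lineage_id is None:
        lineage_id = Path(fasta_path).stem
    return LineageGenome(lineage_id=lineage_id, consensus=consensus,
                         metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# gene-call TSV
# ---------------------------------------------------------------------------

_CALL_COLUMNS = ("lineage_id", "gene_id", "status", "snled", "coverage")


def write_gene_calls(calls: Iterable[GeneCall], path) -> None:
    """Write calls as TSV with columns lineage_id, gene_id, status, snled, coverage."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.lineage_id}\t{c.gene_id}\t{c.status}\t{c.snled!r}\t{c.coverage!r}\n"
            )


def read_gene_calls(path) -> list:
    """Read a gene-call TSV; malformed rows are reported with line numbers."""
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CALL_COLUMNS:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            lineage_id, gene_id, status, snled, coverage = parts
            if status not in STATUSES:
                raise ValueError(f"{path}:{lineno}: invalid status {status!r}")
            try:
                calls.append(
                    GeneCall(gene_id=gene_id, lineage_id=lineage_id, status=status,
                             snled=float(snled), coverage=float(coverage))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return calls


# ---------------------------------------------------------------------------
# pathway definitions
# ---------------------------------------------------------------------------

def read_pathways(path, reference: Reference | None = None) -> list:
    """Read pathway definitions from JSON or YAML.

    Expected shape::

        {"pathways": [{"pathway_id": "biotin",
                       "steps": [{"step_id": "s1", "genes": ["bioA", "bioB"]}],
                       "host_complemented": ["bioH"]}]}
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    out = []
    for entry in data["pathways"]:
        steps = tuple(
            (s["step_id"], frozenset(s["genes"])) for s in entry["steps"]
        )
        pw = PathwayDefinition(
            pathway_id=entry["pathway_id"],
            required_steps=steps,
            host_complemented=frozenset(entry.get("host_complemented", ())),
        )
        if reference is not None:
            pw.validate(set(reference.gene_ids))
        out.append(pw)
    return out
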
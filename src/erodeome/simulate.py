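"""Forward simulator of reductive genome evolution with known ground truth.

Generates a synthetic free-living ancestor (non-overlapping protein-coding
genes on one replicon, GC-controlled) and evolves independent endosymbiont
lineages from it along a branch-length gradient.  The generative process is
the classic two-phase model of endosymbiont genome degeneration: genes are
first inactivated by null mutations (premature stops or small frameshifting
deletions), then the resulting pseudogenes erode away through deletions,
while background substitution pressure is AT-biased.

Constraint sets shape which genes can be lost:

* ``essential`` genes are never inactivated (the universally retained core);
* ``operon`` members are lost quasi-jointly — once one member is hit, the
  others become near-obsolete and inactivate at a boosted hazard (the source
  of *direct* retention relationships);
* ``redundant_pair`` / ``redundant_set`` members back each other up: while
  two or more copies remain the copies are under relaxed selection (boosted
  hazard), but the last surviving member is kept — one or the other may be
  lost, never both (the source of *reciprocal* retention relationships).

Lineages evolve independently from the ancestor (no shared internal tree
structure), matching a comb-like phylogeny with long terminal branches.
Every lineage is driven by its own seed derived from the master seed, so the
set is deterministic and order-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference_io import (
    GeneCall,
    LineageGenome,
    Reference,
    ReferenceGene,
    STOP_CODONS,
    revcomp,
    write_reference,
)

__all__ = [
    "ConstraintSet",
    "SimulationParams",
    "TruthRow",
    "ReplicateSet",
    "generate_ancestor",
    "evolve_lineage",
    "make_replicate_set",
    "default_study_params",
    "truth_to_calls",
]

_STOPS = tuple(sorted(STOP_CODONS))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ConstraintSet:
    """A named group of genes evolving under a shared loss constraint."""

    type: str  # essential | operon | redundant_pair | redundant_set
    gene_ids: tuple

    def __post_init__(self):
        if self.type not in {"essential", "operon", "redundant_pair", "redundant_set"}:
            raise ValueError(f"unknown constraint type {self.type!r}")
        if self.type == "redundant_pair" and len(self.gene_ids) != 2:
            raise ValueError("redundant_pair needs exactly 2 genes")


@dataclass
class SimulationParams:
    """Study conditions for one synthetic replicate set.

    Rates are per unit branch length (substitutions/site).
    ``inactivation_hazard`` is the exponential hazard of a gene acquiring its
    first null mutation; ``erosion_rate`` sets the expected deleted fraction
    of a pseudogene, ``1 - exp(-erosion_rate * residual_branch)``.
    """

    n_genes: int = 500
    gene_length_range: tuple = (100, 200)  # codons, inclusive
    ancestor_gc: float = 0.55
    n_lineages: int = 34
    branch_lengths: tuple = ()
    at_bias: float = 0.8
    inactivation_hazard: float = 3.0
    erosion_rate: float = 4.0
    constraint_sets: tuple = ()
    seed: int = 0
    # secondary knobs (defaults documented in docs/methods.md)
    frameshift_fraction: float = 0.5
    operon_hazard_multiplier: float = 10.0
    redundant_hazard_multiplier: float = 50.0
    deletion_block_mean: int = 200
    spacer_length_range: tuple = (20, 100)
    missing_threshold: float = 0.75
    lesion_window: float = 0.9  # lesions fall in the 5' fraction of the gene

    def __post_init__(self):
        if self.branch_lengths and len(self.branch_lengths) != self.n_lineages:
            raise ValueError("branch_lengths length must equal n_lineages")
        for name in ("at_bias", "ancestor_gc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("inactivation_hazard", "erosion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(b < 0 for b in self.branch_lengths):
            raise ValueError("branch lengths must be >= 0")
        seen = {}
        for cs in self.constraint_sets:
            for g in cs.gene_ids:
                if g in seen:
                    raise ValueError(
                        f"gene {g} appears in more than one constraint set"
                    )
                seen[g] = cs.type


@dataclass
class TruthRow:
    """Ground-truth fate of one gene in one lineage."""

    gene_id: str
    lineage_id: str
    true_status: str  # intact | pseudogene | missing
    inactivating_event: str  # substitution-to-stop | frameshift | deletion | none
    fraction_deleted: float


@dataclass
class ReplicateSet:
    """In-memory handle on a generated replicate set plus its on-disk layout."""

    params: SimulationParams
    reference: Reference
    lineages: list  # list[LineageGenome], metadata carries patristic_distance
    truth: list  # list[TruthRow]
    out_dir: Path | None = None

    def truth_by_pair(self) -> dict:
        return {(t.gene_id, t.lineage_id): t for t in self.truth}


# ---------------------------------------------------------------------------
# ancestor generation
# ---------------------------------------------------------------------------

def _random_bases(rng, n, gc):
    """n iid bases with P(G or C) = gc, uniform within each class."""
    is_gc = rng.random(n) < gc
    pick = rng.integers(0, 2, n)
    bases = np.where(is_gc, np.where(pick == 0, "G", "C"),
                     np.where(pick == 0, "A", "T"))
    return "".join(bases)


def _random_cds(rng, n_codons, gc):
    """ATG + (n_codons-2) non-stop sense codons + a stop codon."""
    body = []
    need = n_codons - 2
    while len(body) < need:
        chunk = _random_bases(rng, 3 * (need - len(body)), gc)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon not in STOP_CODONS:
                body.append(codon)
            if len(body) == need:
                break
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def generate_ancestor(params: SimulationParams, rng=None) -> Reference:
    """Generate the synthetic ancestor: one replicon, ``n_genes`` CDSs.

    Genes are non-overlapping, separated by random intergenic spacers, placed
    on random strands, with coding GC close to ``ancestor_gc`` (within about
    ±0.02 for 200+ genes).  Deterministic given ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 0])
    lo, hi = params.gene_length_range
    if lo < 3:
        raise ValueError("genes need at least 3 codons")
    slo, shi = params.spacer_length_range
    parts, genes, pos = [], [], 0
    spacer = int(rng.integers(slo, shi + 1))
    parts.append(_random_bases(rng, spacer, params.ancestor_gc))
    pos += spacer
    for i in range(params.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        cds = _random_cds(rng, n_codons, params.ancestor_gc)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = cds if strand == "+" else revcomp(cds)
        gene_id = f"g{i + 1:04d}"
        genes.append(
            ReferenceGene(
                gene_id=gene_id, replicon_id="chr", start=pos,
                end=pos + len(cds), strand=strand, cds_seq=cds,
            )
        )
        parts.append(placed)
        pos += len(cds)
        spacer = int(rng.integers(slo, shi + 1))
        parts.append(_random_bases(rng, spacer, params.ancestor_gc))
        pos += spacer
    return Reference(replicons={"chr": "".join(parts)}, genes=genes)


# ---------------------------------------------------------------------------
# lineage evolution
# ---------------------------------------------------------------------------

def _exp_time(rng, rate):
    return math.inf if rate <= 0 else rng.exponential(1.0 / rate)


def _sample_inactivation_times(rng, genes, branch, params):
    """Return {gene_id: time} for genes inactivated before ``branch``,
    honouring essential / operon / redundancy constraints."""
    by_id = {g.gene_id: g for g in genes}
    constrained = set()
    times = {}
    h = params.inactivation_hazard
    for cs in params.constraint_sets:
        members = [g for g in cs.gene_ids if g in by_id]
        constrained.update(members)
        if cs.type == "essential" or not members:
            continue
        if cs.type in ("redundant_pair", "redundant_set"):
            # relaxed selection while a backup copy exists; the last survivor
            # is retained, so losses stop one short of the full set
            t = sorted(
                (_exp_time(rng, h * params.redundant_hazard_multiplier), g)
                for g in members
            )
            for tt, g in t[: len(members) - 1]:
                if tt < branch:
                    times[g] = tt
        elif cs.type == "operon":
            base = [(_exp_time(rng, h), g) for g in members]
            t0 = min(tt for tt, _ in base)
            boosted = h * params.operon_hazard_multiplier
            for tt, g in base:
                if tt == t0:
                    eff = tt
                else:  # obsolescence after the first member falls
                    eff = t0 + _exp_time(rng, boosted) if t0 < branch else tt
                if eff < branch:
                    times[g] = eff
    for g in genes:
        if g.gene_id in constrained:
            continue
        t = _exp_time(rng, h)
        if t < branch:
            times[g.gene_id] = t
    return times


def _reading(chars, gene):
    span = "".join(chars[gene.start : gene.end])
    return span if gene.strand == "+" else revcomp(span)


def _write_reading(chars, gene, reading):
    span = reading if gene.strand == "+" else revcomp(reading)
    chars[gene.start : gene.end] = list(span)


def _apply_lesion(rng, chars, gene, params):
    """Introduce the inactivating null mutation; returns the event label."""
    reading = list(_reading(chars, gene))
    L = len(reading)
    n_codons = L // 3
    hi_codon = max(2, int(params.lesion_window * n_codons))
    if rng.random() < params.frameshift_fraction:
        width = int(rng.integers(1, 3))  # 1-2 bp deletion => frameshift
        p = int(rng.integers(3, max(4, int(params.lesion_window * L))))
        for i in range(p, min(p + width, L - 3)):
            reading[i] = "-"
        event = "frameshift"
    else:
        c = int(rng.integers(1, hi_codon))  # interior codon, 5' 90%
        stop = _STOPS[rng.integers(0, 3)]
        reading[3 * c : 3 * c + 3] = list(stop)
        event = "substitution-to-stop"
    _write_reading(chars, gene, "".join(reading))
    return event


def _apply_erosion(rng, chars, gene, residual, params):
    """Delete geometric blocks of the pseudogene; returns fraction deleted."""
    L = gene.end - gene.start
    target = 1.0 - math.exp(-params.erosion_rate * residual)
    deleted = sum(1 for c in chars[gene.start : gene.end] if c == "-")
    guard = 0
    while deleted < target * L and guard < 500:
        guard += 1
        block = int(rng.geometric(1.0 / params.deletion_block_mean))
        s = gene.start + int(rng.integers(0, L))
        e = min(s + block, gene.end)
        for i in range(s, e):
            if chars[i] != "-":
                chars[i] = "-"
                deleted += 1
    return deleted / L


_BIAS_ALT = {"A": "T", "T": "A", "C": None, "G": None}


def _substitute(rng, chars, gene_index, genes, intact, branch, params):
    """AT-biased background substitutions over one replicon.

    Intact genes are protected from substitutions that would create an
    in-frame premature stop or touch their start/stop codons, so truth-intact
    genes stay translatable.
    """
    if branch <= 0:
        return
    n = len(chars)
    p_sub = 1.0 - math.exp(-branch)
    hits = np.nonzero(rng.random(n) < p_sub)[0]
    coin_bias = rng.random(len(hits))
    coin_pick = rng.integers(0, 3, len(hits))
    arr = chars
    for k, pos in enumerate(hits):
        cur = arr[pos]
        if cur == "-" or cur == "N":
            continue
        if coin_bias[k] < params.at_bias:
            new = _BIAS_ALT[cur]
            if new is None:
                new = "AT"[coin_pick[k] % 2]
        else:
            alts = [b for b in "ACGT" if b != cur]
            new = alts[coin_pick[k]]
        gi = gene_index[pos]
        if gi >= 0 and intact[gi]:
            g = genes[gi]
            if g.strand == "+":
                off = pos - g.start
                base = new
            else:
                off = g.end - 1 - pos
                base = new.translate(_COMPLEMENT)
            ci = off // 3
            n_codons = (g.end - g.start) // 3
            if ci == 0 or ci == n_codons - 1:
                continue  # protect start and stop codons
            reading = _reading(arr, g)
            codon = list(reading[3 * ci : 3 * ci + 3])
            codon[off % 3] = base
            if "".join(codon) in STOP_CODONS:
                continue  # would inactivate a truth-intact gene
        arr[pos] = new


def evolve_lineage(ancestor: Reference, branch_length: float,
                   params: SimulationParams, lineage_seed,
                   lineage_id: str = "lineage") -> tuple:
    """Evolve one lineage from the ancestor along ``branch_length``.

    Returns ``(LineageGenome, list[TruthRow])``.  Inactivation times are
    exponential with the constraint-adjusted hazard; inactivated genes get a
    premature stop or a 1-2 bp frameshifting deletion, then erode by
    geometric deletion blocks over the residual branch; finally AT-biased
    substitutions are applied genome-wide.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = np.random.default_rng(lineage_seed)
    genes = ancestor.genes
    times = _sample_inactivation_times(rng, genes, branch_length, params)

    consensus = {}
    truth = []
    for rid, seq in ancestor.replicons.items():
        chars = list(seq)
        gene_index = np.full(len(seq), -1, dtype=np.int64)
        intact = np.ones(len(genes), dtype=bool)
        for gi, g in enumerate(genes):
            if g.replicon_id == rid:
                gene_index[g.start : g.end] = gi
        for gi, g in enumerate(genes):
            if g.replicon_id != rid:
                continue
            t = times.get(g.gene_id)
            if t is None:
                truth.append(TruthRow(g.gene_id, lineage_id, "intact", "none", 0.0))
                continue
            intact[gi] = False
            event = _apply_lesion(rng, chars, g, params)
            frac = _apply_erosion(rng, chars, g, branch_length - t, params)
            status = "missing" if frac >= params.missing_threshold else "pseudogene"
            if status == "missing":
                event = "deletion"
            truth.append(TruthRow(g.gene_id, lineage_id, status, event, frac))
        _substitute(rng, chars, gene_index, genes, intact, branch_length, params)
        consensus[rid] = "".join(chars)
    truth.sort(key=lambda t: t.gene_id)
    genome = LineageGenome(
        lineage_id=lineage_id, consensus=consensus,
        metadata={"patristic_distance": float(branch_length), "excluded": False},
    )
    return genome, truth


# ---------------------------------------------------------------------------
# replicate sets
# ---------------------------------------------------------------------------

def _branch_gradient(n):
    """Default comb-like gradient: geometric spacing 0.01 -> 0.5."""
    return tuple(np.geomspace(0.01, 0.5, n))


def make_replicate_set(params: SimulationParams, out_dir=None) -> ReplicateSet:
    """Generate ancestor + all lineages; optionally write the directory tree.

    Layout (all plain text): ``ancestor.fasta``, ``ancestor.gff3``,
    ``lineages/<id>.fasta``, ``truth.tsv``, ``metadata.tsv``.  Deterministic
    given ``params`` (per-lineage seeds derive from the master seed, so
    lineages are independent and order-insensitive).
    """
    branches = params.branch_lengths or _branch_gradient(params.n_lineages)
    ancestor = generate_ancestor(params)
    lineages, truth = [], []
    for i, b in enumerate(branches):
        lid = f"L{i:02d}"
        genome, rows = evolve_lineage(
            ancestor, float(b), params, [params.seed, 1, i], lineage_id=lid
        )
        lineages.append(genome)
        truth.extend(rows)

    rep = ReplicateSet(params=params, reference=ancestor, lineages=lineages,
                       truth=truth, out_dir=Path(out_dir) if out_dir else None)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "lineages").mkdir(parents=True, exist_ok=True)
        write_reference(ancestor, out / "ancestor.fasta", out / "ancestor.gff3")
        for genome in lineages:
            with open(out / "lineages" / f"{genome.lineage_id}.fasta", "w") as fh:
                for rid, seq in genome.consensus.items():
                    fh.write(f">{rid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("gene_id\tlineage_id\ttrue_status\tinactivating_event\tfraction_deleted\n")
            for t in sorted(truth, key=lambda t: (t.lineage_id, t.gene_id)):
                fh.write(
                    f"{t.gene_id}\t{t.lineage_id}\t{t.true_status}\t"
                    f"{t.inactivating_event}\t{t.fraction_deleted!r}\n"
                )
        with open(out / "metadata.tsv", "w") as fh:
            fh.write("lineage_id\tpatristic_distance\texcluded\n")
            for genome in lineages:
                fh.write(
                    f"{genome.lineage_id}\t{genome.metadata['patristic_distance']!r}\tFalse\n"
                )
    return rep


def truth_to_calls(truth) -> list:
    """Turn truth rows into perfect GeneCalls (oracle-chaining helper)."""
    out = []
    for t in truth:
        out.append(
            GeneCall(gene_id=t.gene_id, lineage_id=t.lineage_id,
                     status=t.true_status, snled=0.0,
                     coverage=1.0 - t.fraction_deleted)
        )
    return out


def default_study_params(seed: int = 7) -> SimulationParams:
    """The frozen synthetic-study conditions used throughout docs and tests.

    34 lineages x 500 genes on a geometric branch gradient (0.01-0.5
    substitutions/site), AT bias 0.8, inactivation hazard 3, erosion rate 4;
    30 essential genes (doubling as the conserved-ortholog GC set), two
    operons of four genes and five redundant pairs.
    """
    essential = tuple(f"g{i:04d}" for i in range(1, 31))
    operon1 = tuple(f"g{i:04d}" for i in range(41, 45))
    operon2 = tuple(f"g{i:04d}" for i in range(51, 55))
    pairs = [
        (f"g{100 + 2 * k:04d}", f"g{101 + 2 * k:04d}") for k in range(5)
    ]
    constraints = (
        ConstraintSet("essential", essential),
        ConstraintSet("operon", operon1),
        ConstraintSet("operon", operon2),
        *[ConstraintSet("redundant_pair", p) for p in pairs],
    )
    return SimulationParams(
        n_genes=500, n_lineages=34, seed=seed, constraint_sets=constraints
    )
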
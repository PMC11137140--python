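"""Contingency analysis of gene retention strings.

Each fractionally retained gene is a binary string over the included
lineages (1 = intact).  The engine computes:

* the Shannon entropy of each string (base 2, of the Bernoulli frequency),
  used to filter out near-constant strings — the default threshold is the
  entropy of a string with three minority states, which for 34 lineages is
  0.43 bits;
* exhaustive pairwise Hamming distances, where 0 means identical retention
  (co-retention, "direct" relationships) and n means perfectly reciprocal
  retention (functional redundancy resolved in opposite directions);
* the relationship strength ``0.5 * E + (0.5 / (n/2)) * |H - n/2|``, which is
  maximal for high-entropy pairs at either Hamming extreme and minimal at the
  uninformative midpoint H = n/2;
* a Proximus-style recursive bisection clustering of retention patterns in
  which each gene may be complemented before matching, so co-retained and
  reciprocally retained genes land in one cluster with recorded orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RetentionString",
    "GenePairRelation",
    "PatternCluster",
    "shannon_entropy",
    "min_minority_entropy",
    "hamming",
    "relationship_strength",
    "all_relations",
    "cluster_patterns",
    "export_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class RetentionString:
    """One gene's binary retention pattern across lineages."""

    gene_id: str
    bits: tuple
    entropy: float


@dataclass(frozen=True)
class GenePairRelation:
    """Pairwise comparison of two retention strings."""

    gene_a: str
    gene_b: str
    hamming: int
    strength: float
    relation: str  # direct | reciprocal | none
    n: int


@dataclass(frozen=True)
class PatternCluster:
    """A group of genes sharing one retention pattern up to complementation."""

    cluster_id: int
    members: tuple  # gene_ids
    representative: tuple  # bits
    orientation: tuple  # per member: "as-is" | "complemented"
    radius: int


# ---------------------------------------------------------------------------
# scalar primitives
# ---------------------------------------------------------------------------

def shannon_entropy(bits: Sequence[int]) -> float:
    """Base-2 entropy of the Bernoulli frequency of a binary string.

    0 for constant strings, 1 for a balanced string; full precision is kept
    internally — round only at reporting time.
    """
    bits = np.asarray(bits)
    if bits.size == 0:
        raise ValueError("empty retention string")
    p = float(np.mean(bits))
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def min_minority_entropy(n: int, k: int) -> float:
    """Entropy of a length-``n`` binary string with ``k`` minority states.

    ``min_minority_entropy(34, 3)`` is 0.43 at two decimals — the default
    filter threshold requiring at least three lineages with a unique
    functional status.
    """
    if not 0 <= k <= n // 2:
        raise ValueError("k must be between 0 and n//2")
    return shannon_entropy([1] * k + [0] * (n - k))


def hamming(bits_a: Sequence[int], bits_b: Sequence[int]) -> int:
    """Count of differing positions; raises on length mismatch."""
    a = np.asarray(bits_a)
    b = np.asarray(bits_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return int(np.sum(a != b))


def relationship_strength(entropy_a: float, entropy_b: float,
                          hamming_dist: int, n: int) -> float:
    """``0.5 * E_pair + (0.5 / (n/2)) * |H - n/2|`` with E_pair = min(E_a, E_b).

    Taking the smaller of the two entropies prevents a near-constant partner
    from inflating a pair's score.  Bounded in [0, 1]; the constants 17 and
    34 of the n = 34 study generalise to n/2 and n.
    """
    if not 0 <= hamming_dist <= n:
        raise ValueError("hamming distance out of range")
    e_pair = min(entropy_a, entropy_b)
    half = n / 2.0
    return float(0.5 * e_pair + (0.5 / half) * abs(hamming_dist - half))


# ---------------------------------------------------------------------------
# pairwise relations
# ---------------------------------------------------------------------------

def all_relations(matrix, entropy_min="auto", *, k_min: int = 3,
                  direct_max: int = 0, reciprocal_slack: int = 0) -> list:
    """Exhaustive pairwise relations among fractionally retained genes.

    Genes whose string entropy falls below ``entropy_min`` (or, with
    ``"auto"``, below the entropy of ``k_min`` minority lineages) are
    excluded.  A pair is ``direct`` when H <= ``direct_max``, ``reciprocal``
    when H >= n - ``reciprocal_slack``, else ``none``.  The full table is
    returned; the H = n/2 rendering drop is applied by
    :func:`export_edge_list`.
    """
    rm = matrix.fractional()
    bits = rm.binary.to_numpy()
    gene_ids = rm.gene_ids
    n = rm.n_lineages
    if direct_max >= n / 2 or reciprocal_slack >= n / 2:
        raise ValueError("direct/reciprocal bands may not reach the midpoint n/2")
    if entropy_min == "auto":
        entropy_min = min_minority_entropy(n, k_min)
    ent = np.array([shannon_entropy(row) for row in bits])
    keep = np.nonzero(ent >= entropy_min - 1e-12)[0]
    out = []
    for ii, i in enumerate(keep):
        hs = np.sum(bits[keep[ii + 1 :]] != bits[i], axis=1)
        for jj, h in zip(keep[ii + 1 :], hs):
            h = int(h)
            if h <= direct_max:
                rel = "direct"
            elif h >= n - reciprocal_slack:
                rel = "reciprocal"
            else:
                rel = "none"
            out.append(
                GenePairRelation(
                    gene_a=gene_ids[i], gene_b=gene_ids[jj], hamming=h,
                    strength=relationship_strength(ent[i], ent[jj], h, n),
                    relation=rel, n=n,
                )
            )
    return out


def export_edge_list(relations, path, *, drop_midpoint: bool = True) -> None:
    """Write relations as TSV sorted by ascending strength (ties by gene
    ids), so the strongest edges render last; pairs at the uninformative
    midpoint H = n/2 are dropped from this rendering output."""
    rows = [
        r for r in relations
        if not (drop_midpoint and r.n % 2 == 0 and r.hamming == r.n // 2)
    ]
    rows.sort(key=lambda r: (r.strength, r.gene_a, r.gene_b))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\thamming\tstrength\trelation\n")
        for r in rows:
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{r.hamming}\t{float(r.strength)!r}\t{r.relation}\n"
            )


def read_edge_list(path, n: int) -> list:
    """Read an exported edge list back into GenePairRelation rows."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            a, b, h, s, rel = line.rstrip("\n").split("\t")
            out.append(GenePairRelation(a, b, int(h), float(s), rel, n))
    return out


# ---------------------------------------------------------------------------
# pattern clustering
# ---------------------------------------------------------------------------

def _orient(rows, rep):
    """Orient each row toward the representative; ties keep as-is."""
    d = np.sum(rows != rep, axis=1)
    n = rows.shape[1]
    flip = d > n - d
    oriented = np.where(flip[:, None], 1 - rows, rows)
    return oriented, flip


def _representative(rows, seed_row, max_rounds=25):
    """Majority-vote representative under complement canonicalisation.

    Seeded from one member's as-is bits for determinism; majority ties
    resolve to 1 (retained).
    """
    rep = seed_row.copy()
    for _ in range(max_rounds):
        oriented, flip = _orient(rows, rep)
        votes = oriented.sum(axis=0)
        new_rep = (2 * votes >= oriented.shape[0]).astype(rows.dtype)
        if np.array_equal(new_rep, rep):
            break
        rep = new_rep
    oriented, flip = _orient(rows, rep)
    return rep, oriented, flip


def cluster_patterns(matrix, max_radius: int = 0) -> list:
    """Proximus-style recursive bisection of fractional retention patterns.

    Each group gets a majority-vote representative; members are first
    canonicalised to whichever orientation (as-is or complemented) is nearer
    the representative.  Groups whose farthest oriented member exceeds
    ``max_radius`` are split around that member and recursed.  This is a
    simplified radius-bisection in the spirit of Proximus, not a port of it.
    """
    rm = matrix.fractional()
    bits = rm.binary.to_numpy().astype(np.int8)
    gene_ids = np.array(rm.gene_ids)
    if bits.size == 0:
        return []

    clusters = []

    def recurse(idx):
        rows = bits[idx]
        rep, oriented, flip = _representative(rows, rows[0])
        d = np.sum(oriented != rep, axis=1)
        far = int(np.argmax(d))
        if d[far] <= max_radius:
            order = np.argsort(gene_ids[idx])
            clusters.append(
                PatternCluster(
                    cluster_id=-1,
                    members=tuple(gene_ids[idx][order]),
                    representative=tuple(int(v) for v in rep),
                    orientation=tuple(
                        "complemented" if flip[k] else "as-is" for k in order
                    ),
                    radius=int(d.max()),
                )
            )
            return
        seed2 = oriented[far]
        d2 = np.minimum(
            np.sum(rows != seed2, axis=1), np.sum((1 - rows) != seed2, axis=1)
        )
        to_b = d2 < d  # ties stay with the incumbent representative
        to_b[far] = True
        if to_b.all() or not to_b.any():  # degenerate split: peel the outlier
            to_b = np.zeros(len(idx), dtype=bool)
            to_b[far] = True
        recurse(idx[~to_b])
        recurse(idx[to_b])

    recurse(np.arange(len(gene_ids)))
    clusters.sort(key=lambda c: c.members)
    return [
        PatternCluster(cluster_id=i, members=c.members,
                       representative=c.representative,
                       orientation=c.orientation, radius=c.radius)
        for i, c in enumerate(clusters)
    ]
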
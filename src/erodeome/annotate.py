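"""Reference-guided gene-status classification.

For each (gene, lineage) pair the pipeline:

1. extracts the lineage consensus over the reference gene span plus 25 nt of
   flank on each side, collapsing deletion gaps;
2. enumerates candidate ORFs from every canonical/alternative bacterial start
   codon (ATG/GTG/TTG by default) lying within ±25 nt of the reference start,
   each extending to the first in-frame stop;
3. scores every candidate by its Levenshtein edit distance (LED) to the
   reference CDS and keeps the lowest-LED candidate;
4. size-normalises the winning LED by the reference CDS length (snLED);
5. fits a two-component univariate normal mixture to the lineage's snLEDs by
   expectation-maximisation — starting means (0, 1), standard deviations
   (1, 1) — and classifies each gene as intact if its snLED falls at or below
   three standard deviations above the intact-component mean, as missing if
   consensus coverage of the gene is too low, and as a pseudogene otherwise.

Stop codons are excluded from the LED comparison on both sides; the snLED
denominator is the same stop-less reference CDS length, so a fully deleted
gene scores exactly 1.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.special import logsumexp

from .reference_io import (
    GeneCall,
    LineageGenome,
    Reference,
    ReferenceGene,
    STOP_CODONS,
    revcomp,
)

__all__ = [
    "AnnotateConfig",
    "OrfCandidate",
    "MixtureFit",
    "GeneRegion",
    "MixtureError",
    "DegenerateInputError",
    "MixtureCollapseError",
    "extract_gene_region",
    "enumerate_orf_candidates",
    "led",
    "best_candidate",
    "snled",
    "fit_mixture",
    "classify",
    "annotate_lineage",
]

logger = logging.getLogger("erodeome.annotate")

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class AnnotateConfig:
    flank: int = 25
    start_codons: tuple = DEFAULT_START_CODONS
    missing_threshold: float = 0.25  # coverage below this => missing
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    fallback_cutoff: float = 0.02  # fixed snLED cutoff when E-M degenerates
    pooled_fit: bool = False  # fit one mixture across lineages instead of per lineage


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate open reading frame for one gene in one lineage."""

    gene_id: str
    lineage_id: str
    start_offset: int  # nt relative to the reference CDS start (gap-collapsed)
    seq: str  # start codon .. last codon before the first in-frame stop
    start_codon: str
    led: int = -1  # filled by scoring


@dataclass(frozen=True)
class GeneRegion:
    """Gap-collapsed consensus around one gene.

    ``seq`` covers [start - flank, end + flank) in reading orientation with
    '-' removed; ``left_flank`` is the surviving (non-gap) length of the
    5' flank, i.e. the position in ``seq`` aligned to the reference start.
    ``coverage`` is the non-gap, non-N fraction of reference CDS positions.
    """

    seq: str
    left_flank: int
    coverage: float


@dataclass
class MixtureFit:
    """Two-component univariate normal mixture fitted to snLEDs."""

    mean_intact: float
    sd_intact: float
    weight_intact: float
    mean_pseudo: float
    sd_pseudo: float
    loglik: float
    n_iter: int
    converged: bool
    cutoff: float  # mean_intact + 3 * sd_intact
    fallback: bool = False

    @property
    def weight_pseudo(self) -> float:
        return 1.0 - self.weight_intact


class MixtureError(ValueError):
    """Base class for mixture-fit failures that trigger the fixed-cutoff fallback."""


class DegenerateInputError(MixtureError):
    pass


class MixtureCollapseError(MixtureError):
    pass


# ---------------------------------------------------------------------------
# region extraction and ORF enumeration
# ---------------------------------------------------------------------------

def extract_gene_region(lineage: LineageGenome, gene: ReferenceGene,
                        flank: int = 25) -> GeneRegion:
    """Slice the consensus over [start-flank, end+flank), reading orientation.

    Deletion gaps are collapsed out of the returned sequence (N is kept, and
    will count against the LED); the flank is clipped at replicon bounds.
    """
    try:
        consensus = lineage.consensus[gene.replicon_id]
    except KeyError:
        raise KeyError(f"replicon {gene.replicon_id!r} absent from lineage "
                       f"{lineage.lineage_id}") from None
    lo = max(0, gene.start - flank)
    hi = min(len(consensus), gene.end + flank)
    left = consensus[lo : gene.start]
    body = consensus[gene.start : gene.end]
    right = consensus[gene.end : hi]
    if gene.strand == "-":
        left, body, right = revcomp(right), revcomp(body), revcomp(left)
    n_cov = sum(1 for c in body if c not in "-N")
    coverage = n_cov / (gene.end - gene.start)
    left = left.replace("-", "")
    seq = (left + body + right).replace("-", "")
    return GeneRegion(seq=seq, left_flank=len(left), coverage=coverage)


def enumerate_orf_candidates(region: GeneRegion, ref_gene: ReferenceGene,
                             flank: int = 25,
                             starts: Sequence[str] = DEFAULT_START_CODONS,
                             lineage_id: str = "") -> list:
    """All candidate ORFs whose start codon lies within ±flank nt of the
    reference start.

    Each candidate runs from its start codon to the base before the first
    in-frame stop, or to the region end when no stop occurs; candidates
    shorter than two codons are discarded.
    """
    seq = region.seq
    out = []
    lo = max(0, region.left_flank - flank)
    hi = min(len(seq) - 3, region.left_flank + flank)
    for pos in range(lo, hi + 1):
        codon = seq[pos : pos + 3]
        if codon not in starts:
            continue
        end = len(seq)
        for j in range(pos + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                end = j
                break
        cand = seq[pos:end]
        if len(cand) < 6:
            continue
        out.append(
            OrfCandidate(
                gene_id=ref_gene.gene_id, lineage_id=lineage_id,
                start_offset=pos - region.left_flank, seq=cand,
                start_codon=codon,
            )
        )
    return out


def led(a: str, b: str) -> int:
    """Levenshtein edit distance with unit costs (edlib global alignment)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _ref_cds_for_led(ref_gene: ReferenceGene) -> str:
    """Reference CDS without its stop codon (the LED comparison target)."""
    return ref_gene.cds_seq[:-3]


def best_candidate(candidates: Iterable[OrfCandidate],
                   ref_gene: ReferenceGene) -> OrfCandidate | None:
    """Score candidates by LED to the reference CDS and return the minimum.

    Ties break to the longer sequence, then the start offset closest to the
    reference start, then the leftmost.
    """
    ref = _ref_cds_for_led(ref_gene)
    scored = [
        OrfCandidate(gene_id=c.gene_id, lineage_id=c.lineage_id,
                     start_offset=c.start_offset, seq=c.seq,
                     start_codon=c.start_codon, led=led(c.seq, ref))
        for c in candidates
    ]
    if not scored:
        return None
    return min(
        scored,
        key=lambda c: (c.led, -len(c.seq), abs(c.start_offset), c.start_offset),
    )


def snled(led_value: int, ref_gene: ReferenceGene) -> float:
    """Size-normalised LED: LED over the (stop-less) reference CDS length."""
    return led_value / len(_ref_cds_for_led(ref_gene))


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

_SD_FLOOR = 1e-8


def fit_mixture(snleds, tol: float = 1e-8, max_iter: int = 1000) -> MixtureFit:
    """E-M fit of a two-component univariate normal mixture to snLED values.

    Initialisation is fixed at means (0, 1), standard deviations (1, 1) and
    equal weights, bracketing the intact and pseudogene populations.
    Components are relabelled after convergence so that the intact component
    has the smaller mean; the classification cutoff is three standard
    deviations above the intact mean.

    Raises :class:`DegenerateInputError` on constant input (callers should
    fall back to a fixed cutoff) and :class:`MixtureCollapseError` if a
    component's variance collapses during iteration.
    """
    x = np.asarray(list(snleds), dtype=float)
    if x.size < 20:
        raise DegenerateInputError(f"need >= 20 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite snLED values")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise DegenerateInputError("degenerate input: all snLED values identical")

    means = np.array([0.0, 1.0])
    sds = np.array([1.0, 1.0])
    weights = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step in log space
        log_comp = (
            np.log(weights)[:, None]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sds)[:, None]
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk <= 0):
            raise MixtureCollapseError("a component lost all responsibility")
        weights = nk / x.size
        means = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - means**2
        if np.any(var <= _SD_FLOOR**2):
            raise MixtureCollapseError("component variance collapsed")
        sds = np.sqrt(var)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    return MixtureFit(
        mean_intact=float(means[0]), sd_intact=float(sds[0]),
        weight_intact=float(weights[0]), mean_pseudo=float(means[1]),
        sd_pseudo=float(sds[1]), loglik=ll, n_iter=n_iter,
        converged=converged, cutoff=float(means[0] + 3 * sds[0]),
    )


def _fallback_fit(cutoff: float, reason: str) -> MixtureFit:
    logger.warning("mixture fit fell back to fixed cutoff %.4g (%s)", cutoff, reason)
    return MixtureFit(
        mean_intact=0.0, sd_intact=0.0, weight_intact=1.0, mean_pseudo=1.0,
        sd_pseudo=0.0, loglik=float("nan"), n_iter=0, converged=True,
        cutoff=cutoff, fallback=True,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(calls, fit: MixtureFit, missing_threshold: float = 0.25) -> list:
    """Assign statuses: low coverage => missing; snLED <= cutoff => intact
    (inclusive boundary); otherwise pseudogene."""
    out = []
    for c in calls:
        if c.coverage < missing_threshold:
            status = "missing"
        elif c.snled <= fit.cutoff:
            status = "intact"
        else:
            status = "pseudogene"
        out.append(
            GeneCall(gene_id=c.gene_id, lineage_id=c.lineage_id, status=status,
                     snled=c.snled, coverage=c.coverage,
                     best_candidate=c.best_candidate)
        )
    return out


def _score_gene(lineage, gene, config) -> GeneCall:
    region = extract_gene_region(lineage, gene, config.flank)
    cands = enumerate_orf_candidates(
        region, gene, config.flank, config.start_codons, lineage.lineage_id
    )
    best = best_candidate(cands, gene)
    if best is not None:
        led_value = best.led
    else:
        # no valid start in the window: score the gap-collapsed gene body so
        # the gene still enters the mixture as a high-snLED point
        body_len = _collapsed_body_len(lineage, gene)
        body = region.seq[region.left_flank : region.left_flank + body_len]
        led_value = led(body, _ref_cds_for_led(gene))
    return GeneCall(
        gene_id=gene.gene_id, lineage_id=lineage.lineage_id, status="intact",
        snled=snled(led_value, gene), coverage=region.coverage,
        best_candidate=best,
    )


def _collapsed_body_len(lineage, gene) -> int:
    body = lineage.consensus[gene.replicon_id][gene.start : gene.end]
    return len(body) - body.count("-")


def annotate_lineage(lineage: LineageGenome, reference: Reference,
                     config: AnnotateConfig | None = None) -> tuple:
    """Score and classify every reference gene in one lineage.

    Returns ``(calls, fit)`` with one :class:`~erodeome.reference_io.GeneCall`
    per reference gene.  The mixture is fitted over this lineage's snLEDs,
    excluding genes below the coverage threshold; degenerate fits (e.g.
    self-annotation of the reference, where every snLED is 0) fall back to a
    fixed cutoff.
    """
    config = config or AnnotateConfig()
    raw = [_score_gene(lineage, g, config) for g in reference.genes]
    in_fit = [c.snled for c in raw if c.coverage >= config.missing_threshold]
    try:
        fit = fit_mixture(in_fit, tol=config.em_tol, max_iter=config.em_max_iter)
    except MixtureError as exc:
        fit = _fallback_fit(config.fallback_cutoff, str(exc))
    logger.info(
        "lineage %s: mixture intact N(%.4f, %.4f) w=%.3f | pseudo N(%.4f, %.4f) "
        "| cutoff %.4f%s",
        lineage.lineage_id, fit.mean_intact, fit.sd_intact, fit.weight_intact,
        fit.mean_pseudo, fit.sd_pseudo, fit.cutoff,
        " [fallback]" if fit.fallback else "",
    )
    return classify(raw, fit, config.missing_threshold), fit
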
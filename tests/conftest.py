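"""Shared fixtures: a tiny hand-built reference and the full synthetic study.

The session-scoped ``study`` fixture runs the frozen synthetic study once
(34 lineages x 500 genes, seed 7) — simulation, per-lineage annotation and
retention-matrix assembly — and is shared by the simulator, retention,
contingency and acceptance tests.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from erodeome import annotate as A
from erodeome import retention as R
from erodeome import simulate as S
from erodeome.reference_io import LineageGenome, Reference, ReferenceGene

# planted structure of the default study (see simulate.default_study_params)
ESSENTIAL = tuple(f"g{i:04d}" for i in range(1, 31))
OPERONS = (
    tuple(f"g{i:04d}" for i in range(41, 45)),
    tuple(f"g{i:04d}" for i in range(51, 55)),
)
REDUNDANT_PAIRS = tuple(
    (f"g{100 + 2 * k:04d}", f"g{101 + 2 * k:04d}") for k in range(5)
)


@dataclass
class Study:
    params: S.SimulationParams
    rep: S.ReplicateSet
    calls_by_lineage: dict  # lineage_id -> list[GeneCall]
    fits: dict  # lineage_id -> MixtureFit
    matrix: R.RetentionMatrix
    branches: dict  # lineage_id -> branch length

    @property
    def all_calls(self):
        return [c for calls in self.calls_by_lineage.values() for c in calls]


@pytest.fixture(scope="session")
def study() -> Study:
    params = S.default_study_params(seed=7)
    rep = S.make_replicate_set(params)
    calls_by_lineage, fits = {}, {}
    for genome in rep.lineages:
        calls, fit = A.annotate_lineage(genome, rep.reference)
        calls_by_lineage[genome.lineage_id] = calls
        fits[genome.lineage_id] = fit
    matrix = R.build_matrix(
        [c for calls in calls_by_lineage.values() for c in calls]
    )
    branches = {
        g.lineage_id: g.metadata["patristic_distance"] for g in rep.lineages
    }
    return Study(params=params, rep=rep, calls_by_lineage=calls_by_lineage,
                 fits=fits, matrix=matrix, branches=branches)


# ---------------------------------------------------------------------------
# hand-built toy reference
# ---------------------------------------------------------------------------

TOY_CDS = "ATG" + "AAACCCGGGTTTACACATGCACTT" + "TAA"  # 30 nt, 10 codons


def toy_reference(strand: str = "+") -> Reference:
    """120 bp replicon with one valid 30 nt CDS at [3, 33)."""
    placed = TOY_CDS if strand == "+" else _rc(TOY_CDS)
    seq = "CCA" + placed + ("ACGT" * 22)[:87]
    gene = ReferenceGene(
        gene_id="geneA", replicon_id="chr", start=3, end=33, strand=strand,
        cds_seq=TOY_CDS,
    )
    return Reference(replicons={"chr": seq}, genes=[gene])


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def as_lineage(reference: Reference, lineage_id="self") -> LineageGenome:
    """The reference itself, viewed as an (undiverged) lineage consensus."""
    return LineageGenome(lineage_id=lineage_id,
                         consensus=dict(reference.replicons))
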
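"""Entropy, Hamming, relationship strength, relations and pattern clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from erodeome import contingency as C
from erodeome import retention as R
from erodeome import simulate as S

from conftest import OPERONS, REDUNDANT_PAIRS

bit_strings = st.lists(st.integers(0, 1), min_size=1, max_size=12)


def _matrix_from_bits(rows, gene_ids=None):
    """Build a RetentionMatrix from binary rows (1 -> intact, 0 -> pseudogene)."""
    rows = np.asarray(rows)
    gene_ids = gene_ids or [f"g{i}" for i in range(rows.shape[0])]
    status = pd.DataFrame(
        np.where(rows == 1, "I", "P"), index=gene_ids,
        columns=[f"L{j}" for j in range(rows.shape[1])],
    )
    return R.RetentionMatrix(status)


class TestShannonEntropy:
    def test_three_of_34_rounds_to_the_filter_threshold(self):
        e = C.shannon_entropy([1] * 3 + [0] * 31)
        assert round(e, 2) == 0.43

    def test_constant_string_has_zero_entropy(self):
        assert C.shannon_entropy([1] * 10) == 0.0
        assert C.shannon_entropy([0] * 34) == 0.0

    def test_balanced_string_has_unit_entropy(self):
        assert C.shannon_entropy([1] * 17 + [0] * 17) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(bit_strings)
    def test_complement_symmetry(self, bits):
        comp = [1 - b for b in bits]
        assert C.shannon_entropy(bits) == pytest.approx(C.shannon_entropy(comp))

    def test_agrees_with_scipy_entropy(self):
        for n, k in [(34, 3), (20, 7), (12, 6), (9, 1)]:
            mine = C.shannon_entropy([1] * k + [0] * (n - k))
            theirs = sps.entropy([k, n - k], base=2)
            assert mine == pytest.approx(theirs)


class TestMinMinorityEntropy:
    def test_reference_values(self):
        assert round(C.min_minority_entropy(34, 3), 2) == 0.43
        assert C.min_minority_entropy(20, 0) == 0.0
        p = 3 / 20
        direct = -p * math.log2(p) - (1 - p) * math.log2(1 - p)
        assert C.min_minority_entropy(20, 3) == pytest.approx(direct)

    def test_rejects_majority_k(self):
        with pytest.raises(ValueError):
            C.min_minority_entropy(10, 6)


class TestHamming:
    def test_identical_and_complement_extremes(self):
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, 34)
        assert C.hamming(bits, bits) == 0
        assert C.hamming(bits, 1 - bits) == 34

    def test_example(self):
        assert C.hamming([0, 1, 0, 1], [1, 0, 1, 0]) == 4

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            C.hamming([0, 1], [0, 1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.data())
    def test_metric_and_complement_identities(self, n, data):
        draw = lambda: data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        a, b, c = draw(), draw(), draw()
        assert C.hamming(a, b) == C.hamming(b, a)
        assert C.hamming(a, a) == 0
        assert C.hamming(a, c) <= C.hamming(a, b) + C.hamming(b, c)
        comp_b = [1 - x for x in b]
        assert C.hamming(a, comp_b) == n - C.hamming(a, b)


class TestRelationshipStrength:
    @pytest.mark.parametrize(
        "e,h,expected",
        [
            (0.0, 0, 0.5), (0.0, 17, 0.0), (0.0, 34, 0.5),
            (0.43, 0, 0.715), (0.43, 17, 0.215), (0.43, 34, 0.715),
            (1.0, 0, 1.0), (1.0, 17, 0.5), (1.0, 34, 1.0),
        ],
    )
    def test_grid_matches_direct_arithmetic(self, e, h, expected):
        assert C.relationship_strength(e, e, h, 34) == pytest.approx(expected)

    def test_maximal_only_at_high_entropy_extremes(self):
        grid = [
            (e, h) for e in (0.0, 0.43, 1.0) for h in (0, 17, 34)
        ]
        vals = {(e, h): C.relationship_strength(e, e, h, 34) for e, h in grid}
        top = {k for k, v in vals.items() if v == pytest.approx(1.0)}
        assert top == {(1.0, 0), (1.0, 34)}

    def test_bounded_and_monotone(self):
        for n in (10, 34, 35):
            prev_by_h = None
            for e in np.linspace(0, 1, 6):
                for h in range(n + 1):
                    v = C.relationship_strength(e, e, h, n)
                    assert 0.0 <= v <= 1.0 + 1e-12
            # non-decreasing in |H - n/2| at fixed entropy
            vals = [C.relationship_strength(0.5, 0.5, h, n) for h in range(n + 1)]
            half = n / 2
            ordered = sorted(range(n + 1), key=lambda h: abs(h - half))
            seq = [vals[h] for h in ordered]
            assert all(x <= y + 1e-12 for x, y in zip(seq, seq[1:]))

    def test_uses_the_smaller_entropy_of_the_pair(self):
        assert C.relationship_strength(0.1, 1.0, 0, 34) == pytest.approx(
            C.relationship_strength(0.1, 0.1, 0, 34)
        )


class TestAllRelations:
    def test_identical_high_entropy_strings_are_direct(self):
        row = [1] * 6 + [0] * 6
        m = _matrix_from_bits([row, row, [1] * 11 + [0]])
        rels = C.all_relations(m, entropy_min=0.3)
        rel = {(r.gene_a, r.gene_b): r for r in rels}
        assert rel[("g0", "g1")].relation == "direct"
        assert rel[("g0", "g1")].hamming == 0

    def test_complement_is_reciprocal_at_full_distance(self):
        row = [1] * 6 + [0] * 6
        comp = [1 - b for b in row]
        m = _matrix_from_bits([row, comp])
        (rel,) = C.all_relations(m, entropy_min=0.3)
        assert rel.relation == "reciprocal" and rel.hamming == 12

    def test_low_entropy_genes_are_filtered(self):
        m = _matrix_from_bits(
            [[1] * 32 + [0] * 2, [0] * 2 + [1] * 32, [1] * 17 + [0] * 17]
        )
        rels = C.all_relations(m, entropy_min="auto", k_min=3)
        assert rels == []  # the 2-of-34 genes fail the filter; no pair remains

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for n_genes, n_lin in [(12, 10), (50, 12)]:
            bits = rng.integers(0, 2, (n_genes, n_lin))
            m = _matrix_from_bits(bits, gene_ids=[f"g{i:03d}" for i in range(n_genes)])
            got = {
                (r.gene_a, r.gene_b): (r.hamming, r.strength, r.relation)
                for r in C.all_relations(m, entropy_min=0.3, direct_max=1,
                                         reciprocal_slack=1)
            }
            # oracle: plain double loop with inline formulas
            frac = [
                i for i in range(n_genes) if 0 < bits[i].sum() < n_lin
            ]
            ent = {}
            for i in frac:
                p = bits[i].mean()
                ent[i] = -p * math.log2(p) - (1 - p) * math.log2(1 - p)
            expected = {}
            kept = [i for i in frac if ent[i] >= 0.3]
            for i, j in itertools.combinations(kept, 2):
                h = int((bits[i] != bits[j]).sum())
                e = min(ent[i], ent[j])
                s = 0.5 * e + (0.5 / (n_lin / 2)) * abs(h - n_lin / 2)
                rel = (
                    "direct" if h <= 1
                    else "reciprocal" if h >= n_lin - 1 else "none"
                )
                expected[(f"g{i:03d}", f"g{j:03d}")] = (h, s, rel)
            assert got.keys() == expected.keys()
            for k in expected:
                assert got[k][0] == expected[k][0]
                assert got[k][1] == pytest.approx(expected[k][1])
                assert got[k][2] == expected[k][2]

    def test_band_may_not_reach_the_midpoint(self):
        m = _matrix_from_bits([[1, 0] * 6, [0, 1] * 6])
        with pytest.raises(ValueError, match="midpoint"):
            C.all_relations(m, entropy_min=0.0, direct_max=6)


class TestEdgeList:
    def _rels(self):
        return [
            C.GenePairRelation("a", "b", 0, 0.9, "direct", 12),
            C.GenePairRelation("a", "c", 6, 0.2, "none", 12),  # H == n/2
            C.GenePairRelation("b", "c", 12, 0.9, "reciprocal", 12),
            C.GenePairRelation("a", "d", 3, 0.4, "none", 12),
        ]

    def test_round_trip_and_strength_sort(self, tmp_path):
        p = tmp_path / "edges.tsv"
        C.export_edge_list(self._rels(), p, drop_midpoint=False)
        back = C.read_edge_list(p, n=12)
        assert [r.strength for r in back] == sorted(r.strength for r in self._rels())
        # equal strengths tie-break on gene ids
        assert [(r.gene_a, r.gene_b) for r in back[-2:]] == [("a", "b"), ("b", "c")]

    def test_midpoint_pairs_dropped_from_rendering_output(self, tmp_path):
        p = tmp_path / "edges.tsv"
        C.export_edge_list(self._rels(), p)
        back = C.read_edge_list(p, n=12)
        assert all(r.hamming != 6 for r in back)
        assert len(back) == 3

    def test_empty_relations_write_header_only(self, tmp_path):
        p = tmp_path / "edges.tsv"
        C.export_edge_list([], p)
        assert p.read_text() == "gene_a\tgene_b\thamming\tstrength\trelation\n"


class TestClusterPatterns:
    def test_complemented_copies_fold_into_one_cluster(self):
        row = [1, 0, 1, 1, 0, 0, 1, 0]
        comp = [1 - b for b in row]
        m = _matrix_from_bits([row] * 10 + [comp] * 10)
        (cluster,) = C.cluster_patterns(m, max_radius=0)
        assert len(cluster.members) == 20
        assert sum(o == "complemented" for o in cluster.orientation) == 10
        assert cluster.radius == 0

    def test_distant_patterns_split_into_separate_clusters(self):
        a = [1] * 6 + [0] * 6
        b = [1, 0] * 6
        # oriented distance between the patterns exceeds 2 * max_radius
        assert min(C.hamming(a, b), 12 - C.hamming(a, b)) > 2
        m = _matrix_from_bits([a, a, b, b])
        clusters = C.cluster_patterns(m, max_radius=1)
        assert len(clusters) == 2
        assert all(c.radius <= 1 for c in clusters)

    def test_empty_input_gives_empty_list(self):
        m = _matrix_from_bits([[1] * 8, [0] * 8])  # nothing fractional
        assert C.cluster_patterns(m, max_radius=0) == []

    def test_radius_bound_is_respected_everywhere(self, study):
        clusters = C.cluster_patterns(study.matrix, max_radius=2)
        bits = study.matrix.fractional().binary
        for c in clusters:
            rep = np.array(c.representative)
            for gid, orient in zip(c.members, c.orientation):
                row = bits.loc[gid].to_numpy()
                if orient == "complemented":
                    row = 1 - row
                assert C.hamming(row, rep) <= 2


@pytest.fixture(scope="module")
def planted():
    """Small simulated matrix with planted operons and redundant pairs."""
    ids = lambda a, b: tuple(f"g{i:04d}" for i in range(a, b))
    cons = (
        S.ConstraintSet("operon", ids(5, 9)),
        S.ConstraintSet("operon", ids(11, 15)),
        *[
            S.ConstraintSet("redundant_pair", (f"g{20 + 2 * k:04d}", f"g{21 + 2 * k:04d}"))
            for k in range(3)
        ],
    )
    params = S.SimulationParams(
        n_genes=60, n_lineages=30,
        branch_lengths=tuple(np.geomspace(0.02, 0.4, 30)),
        seed=13, constraint_sets=cons, operon_hazard_multiplier=100.0,
    )
    rep = S.make_replicate_set(params)
    matrix = R.build_matrix(S.truth_to_calls(rep.truth))
    return cons, matrix


class TestPlantedStructureRecovery:
    """End-to-end contingency recovery on simulated data with known truth."""

    def test_pairs_reciprocal_and_operons_direct(self, planted):
        cons, matrix = planted
        rels = C.all_relations(matrix, entropy_min="auto", direct_max=2,
                               reciprocal_slack=2)
        idx = {frozenset((r.gene_a, r.gene_b)): r.relation for r in rels}
        for cs in cons:
            if cs.type == "redundant_pair":
                assert idx[frozenset(cs.gene_ids)] == "reciprocal"
            elif cs.type == "operon":
                for a, b in itertools.combinations(cs.gene_ids, 2):
                    assert idx[frozenset((a, b))] == "direct"

    def test_pairs_co_cluster_with_opposite_orientations(self, planted):
        cons, matrix = planted
        clusters = C.cluster_patterns(matrix, max_radius=2)
        memb = {g: c.cluster_id for c in clusters for g in c.members}
        orient = {
            g: o for c in clusters for g, o in zip(c.members, c.orientation)
        }
        for cs in cons:
            if cs.type == "redundant_pair":
                a, b = cs.gene_ids
                assert memb[a] == memb[b]
                assert orient[a] != orient[b]
            elif cs.type == "operon":
                ms = {memb[g] for g in cs.gene_ids}
                os = {orient[g] for g in cs.gene_ids}
                assert len(ms) == 1 and len(os) == 1
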
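"""The alignment engine: neighborhoods, Gotoh alignment (vs an exhaustive
oracle), evidence accumulation, candidate selection, clustering, Ncorr5."""

from itertools import combinations

import numpy as np
import pytest

from slam.annotation import DabeKey, annotate_structure
from slam.config import SlamConfig
from slam.core import (
    Alignment3D,
    PairScoreTable,
    _gotoh,
    accumulate_pair_evidence,
    align_sequences,
    build_neighborhoods,
    cluster_pairs,
    distance_correlation,
    ncorr5,
    select_candidate_pairs,
    slam_align,
)
from slam.errors import DegenerateCorrelationError, ExtractionError
from slam.pipeline import structure_as_substructure
from slam.structure import AnnotatedAtom, Substructure

from conftest import rigid_copy


def make_sub(coords, elements=None, groups=None, dabes=None, chain="A"):
    """Substructure of single-atom residues at the given coordinates."""
    atoms = []
    n = len(coords)
    elements = elements or ["C"] * n
    for i, (xyz, el) in enumerate(zip(coords, elements), start=1):
        a = AnnotatedAtom(
            atom_id=f"{chain}:{i}:CA", name="CA", element=el,
            coords=np.asarray(xyz, dtype=float), chain_id=chain,
            residue_name="GLY", residue_seq=i,
        )
        a.aa_group = groups[i - 1] if groups else 1
        a.dabe = dabes[i - 1] if dabes else DabeKey(0, 0, 1, 0)
        atoms.append(a)
    return Substructure("toy", chain, "surface_patch", atoms, "toy")


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------

class TestNeighborhoods:
    def test_collinear_sequence_order(self):
        sub = make_sub([(float(x), 0.0, 0.0) for x in range(9)])
        neigh = build_neighborhoods(sub, k=7)
        first = neigh[0]
        assert first.distances == pytest.approx(list(range(1, 8)))
        assert first.sequence_ids == [f"A:{i}:CA" for i in range(2, 9)]

    def test_equidistant_ties_break_by_atom_id(self):
        # symmetric cross: four arms at distance 1 from the center
        coords = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                  (0, 0, 1), (0, 0, -1), (2, 0, 0), (0, 2, 0)]
        sub = make_sub(coords)
        n1 = build_neighborhoods(sub, k=7)
        n2 = build_neighborhoods(sub, k=7)
        assert n1[0].sequence_ids == n2[0].sequence_ids
        tied = n1[0].sequence_ids[:6]
        assert tied == sorted(tied)

    def test_minimal_substructure_uses_all_atoms(self):
        sub = make_sub([(float(x), 0.0, 0.0) for x in range(8)])
        for nb in build_neighborhoods(sub, k=7):
            assert len(nb) == 7
            assert nb.center not in nb.sequence_ids

    def test_too_small_substructure_raises(self):
        sub = make_sub([(float(x), 0.0, 0.0) for x in range(5)])
        with pytest.raises(ExtractionError):
            build_neighborhoods(sub, k=7)

    def test_distances_non_decreasing_everywhere(self, toy_substructure):
        for nb in build_neighborhoods(toy_substructure, k=7):
            assert all(
                d2 >= d1 for d1, d2 in zip(nb.distances, nb.distances[1:])
            )


# ---------------------------------------------------------------------------
# alignment vs exhaustive oracle
# ---------------------------------------------------------------------------

def alignment_oracle(S, gap_open, gap_extend):
    """Best global alignment score by enumerating all monotone matchings."""
    la, lb = S.shape

    def g(L):
        return 0.0 if L == 0 else gap_open + gap_extend * (L - 1)

    best = -np.inf
    for k in range(0, min(la, lb) + 1):
        for rows in combinations(range(la), k):
            for cols in combinations(range(lb), k):
                score = sum(S[r, c] for r, c in zip(rows, cols))
                pr = pc = -1
                for r, c in zip(rows + (la,), cols + (lb,)):
                    score += g(r - pr - 1) + g(c - pc - 1)
                    pr, pc = r, c
                best = max(best, score)
    return best


def rescore_traceback(S, pairs, gap_open, gap_extend):
    la, lb = S.shape

    def g(L):
        return 0.0 if L == 0 else gap_open + gap_extend * (L - 1)

    score = sum(S[i, j] for i, j in pairs)
    pr = pc = -1
    for i, j in list(pairs) + [(la, lb)]:
        score += g(i - pr - 1) + g(j - pc - 1)
        pr, pc = i, j
    return score


class TestGotoh:
    @pytest.mark.parametrize("case", range(40))
    def test_matches_exhaustive_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        la, lb = rng.integers(1, 6, size=2)
        S = rng.uniform(0.0, 8.0, size=(la, lb)).round(2)
        score, pairs, _ = _gotoh(S, -4.0, -1.0)
        assert score == pytest.approx(alignment_oracle(S, -4.0, -1.0))
        # traceback consistency and monotonicity
        assert score == pytest.approx(rescore_traceback(S, pairs, -4.0, -1.0))
        assert all(
            p2[0] > p1[0] and p2[1] > p1[1] for p1, p2 in zip(pairs, pairs[1:])
        )

    def test_identity_alignment(self, model, toy_substructure):
        nb = build_neighborhoods(toy_substructure, k=7)[0]
        atoms = [toy_substructure.atoms[i] for i in nb.sequence]
        al = align_sequences(atoms, atoms, model)
        assert len(al.matched_pairs) == 7
        assert al.gaps == 0
        assert all(a == b for a, b in al.matched_pairs)

    def test_self_alignment_is_an_upper_bound(self, model, toy_substructure):
        neigh = build_neighborhoods(toy_substructure, k=7)
        a1 = [toy_substructure.atoms[i] for i in neigh[0].sequence]
        a2 = [toy_substructure.atoms[i] for i in neigh[11].sequence]
        cross = align_sequences(a1, a2, model).score
        self1 = align_sequences(a1, a1, model).score
        self2 = align_sequences(a2, a2, model).score
        assert cross <= min(self1, self2) + 1e-9


# ---------------------------------------------------------------------------
# evidence and candidate selection
# ---------------------------------------------------------------------------

class TestEvidence:
    def test_self_screen_diagonal_dominates(self, model, toy_substructure):
        table = accumulate_pair_evidence(
            toy_substructure, toy_substructure, model
        )
        top_pair = max(table.evidence.items(), key=lambda kv: kv[1])[0]
        assert top_pair[0] == top_pair[1]
        diag = [v for (a, b), v in table.evidence.items() if a == b]
        off = [v for (a, b), v in table.evidence.items() if a != b]
        assert np.median(diag) > np.median(off)

    def test_disjoint_chemistry_gives_empty_table(self, model):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3)) * 4.0
        sub_a = make_sub(coords, groups=[2] * 10,
                         dabes=[DabeKey(1, 1, 1, 1)] * 10, chain="A")
        sub_b = make_sub(coords + 50.0, groups=[4] * 10,
                         dabes=[DabeKey(0, 0, 0, 0)] * 10, chain="B")
        table = accumulate_pair_evidence(sub_a, sub_b, model)
        assert len(table.evidence) == 0

    def test_stored_evidence_is_positive_with_counts(self, model, toy_substructure):
        table = accumulate_pair_evidence(toy_substructure, toy_substructure, model)
        assert all(v > 0 for v in table.evidence.values())
        assert all(c >= 1 for c in table.n_alignments.values())


class TestCandidateSelection:
    def test_outlier_separation_worked_example(self):
        table = PairScoreTable()
        for i, v in enumerate([1, 1, 1, 1, 100, 100]):
            table.add((f"a{i}", f"b{i}"), v)
        selected = select_candidate_pairs(table)
        assert sorted(selected) == [("a4", "b4"), ("a5", "b5")]

    def test_empty_table_gives_empty_selection(self):
        assert select_candidate_pairs(PairScoreTable()) == []

    def test_uniform_background_selects_nothing(self):
        table = PairScoreTable()
        for i in range(20):
            table.add((f"a{i}", f"b{i}"), 5.0)
        assert select_candidate_pairs(table) == []

    def test_mean_sd_policy(self):
        table = PairScoreTable()
        for i in range(10):
            table.add((f"a{i}", f"b{i}"), 0.0)
        table.add(("x", "y"), 50.0)
        assert select_candidate_pairs(table, policy="mean_sd") == [("x", "y")]

    def test_quantile_and_fixed_policies(self):
        table = PairScoreTable()
        for i in range(100):
            table.add((f"a{i}", f"b{i}"), float(i))
        q = select_candidate_pairs(table, policy="quantile", quantile=0.05)
        assert len(q) == 5
        f = select_candidate_pairs(table, policy="fixed", fixed=97.5)
        assert sorted(f) == [("a98", "b98"), ("a99", "b99")]


# ---------------------------------------------------------------------------
# distance correlation and clustering
# ---------------------------------------------------------------------------

class TestDistanceCorrelation:
    def _coords(self, pts, chain="A"):
        return {f"{chain}:{i + 1}:CA": np.asarray(p, float) for i, p in enumerate(pts)}

    def test_rigid_transform_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3)) * 5.0
        M = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        pts_b = pts @ M.T + 7.0
        ca = self._coords(pts)
        cb = self._coords(pts_b, "B")
        pairs = [(f"A:{i + 1}:CA", f"B:{i + 1}:CA") for i in range(8)]
        assert distance_correlation(pairs, ca, cb) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_scaling_keeps_unit_correlation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3)) * 5.0
        pairs = [(f"A:{i + 1}:CA", f"B:{i + 1}:CA") for i in range(6)]
        assert distance_correlation(
            pairs, self._coords(pts), self._coords(pts * 2.0, "B")
        ) == pytest.approx(1.0, abs=1e-9)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(4)
        pa = rng.normal(size=(10, 3)) * 5.0
        pb = rng.normal(size=(10, 3)) * 5.0
        pairs = [(f"A:{i + 1}:CA", f"B:{i + 1}:CA") for i in range(10)]
        r = distance_correlation(pairs, self._coords(pa), self._coords(pb, "B"))
        da = [np.linalg.norm(pa[i] - pa[j]) for i in range(10) for j in range(i + 1, 10)]
        db = [np.linalg.norm(pb[i] - pb[j]) for i in range(10) for j in range(i + 1, 10)]
        expected = np.corrcoef(da, db)[0, 1]
        assert abs(r) < 1.0
        assert r == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        ca = self._coords([(0, 0, 0), (1, 0, 0)])
        cb = self._coords([(0, 0, 0), (1, 0, 0)], "B")
        with pytest.raises(DegenerateCorrelationError):
            distance_correlation([("A:1:CA", "B:1:CA"), ("A:2:CA", "B:2:CA")], ca, cb)
        # equilateral triangle: zero-variance distance vector
        tri = [(0, 0, 0), (1, 0, 0), (0.5, np.sqrt(3) / 2, 0)]
        pairs = [(f"A:{i + 1}:CA", f"B:{i + 1}:CA") for i in range(3)]
        with pytest.raises(DegenerateCorrelationError):
            distance_correlation(pairs, self._coords(tri), self._coords(tri, "B"))


class TestClustering:
    def test_two_disjoint_motifs_stay_separate(self):
        # two rigid motifs, far apart on the A side but mapped into the
        # same region on the B side: their cross distances are mutually
        # inconsistent, so any merged group falls below the r threshold
        rng = np.random.default_rng(7)
        p1 = rng.normal(size=(8, 3)) * 4.0
        p2 = rng.normal(size=(8, 3)) * 4.0 + np.array([60.0, 0, 0])
        M1 = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        M2 = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        q1 = (p1 - p1.mean(0)) @ M1.T + np.array([0.0, 60.0, 0.0])
        q2 = (p2 - p2.mean(0)) @ M2.T + np.array([12.0, 60.0, 0.0])
        ca = {f"A:{i + 1}:CA": c for i, c in enumerate(np.vstack([p1, p2]))}
        cb = {f"B:{i + 1}:CA": c for i, c in enumerate(np.vstack([q1, q2]))}
        pairs = [(f"A:{i + 1}:CA", f"B:{i + 1}:CA") for i in range(16)]
        clusters = cluster_pairs(pairs, ca, cb)
        assert len(clusters) >= 2
        top_two = [frozenset(al.pairs) for al in clusters[:2]]
        motif1 = frozenset(pairs[:8])
        motif2 = frozenset(pairs[8:])
        assert motif1 in top_two and motif2 in top_two

    def test_single_candidate_is_below_minimum(self):
        ca = {"A:1:CA": np.zeros(3)}
        cb = {"B:1:CA": np.zeros(3)}
        assert cluster_pairs([("A:1:CA", "B:1:CA")], ca, cb) == []

    def test_emitted_clusters_are_one_to_one(self, toy_substructure, toy_structure):
        s2 = rigid_copy(toy_structure, 42)
        als = slam_align(toy_substructure, structure_as_substructure(s2))
        for al in als:
            a_side = [a for a, _ in al.pairs]
            b_side = [b for _, b in al.pairs]
            assert len(set(a_side)) == len(a_side)
            assert len(set(b_side)) == len(b_side)
            assert al.r > 0.85


# ---------------------------------------------------------------------------
# scoring and the full pipeline
# ---------------------------------------------------------------------------

class TestNcorr5:
    def test_formula_values(self):
        assert ncorr5(Alignment3D([("a", "b")] * 40, r=0.9, ncorr5=0)) == pytest.approx(23.6196)
        assert ncorr5(Alignment3D([("a", "b")] * 12, r=1.0, ncorr5=0)) == pytest.approx(12.0)
        assert ncorr5(Alignment3D([("a", "b")] * 35, r=0.95, ncorr5=0)) == pytest.approx(27.0823, abs=1e-3)

    def test_monotonic_in_n_and_r(self):
        base = ncorr5(Alignment3D([("a", "b")] * 20, r=0.9, ncorr5=0))
        assert ncorr5(Alignment3D([("a", "b")] * 21, r=0.9, ncorr5=0)) > base
        assert ncorr5(Alignment3D([("a", "b")] * 20, r=0.95, ncorr5=0)) > base


class TestSlamAlign:
    def test_self_screen_recovers_identity(self, toy_structure, toy_substructure):
        s2 = rigid_copy(toy_structure, 11)
        als = slam_align(toy_substructure, structure_as_substructure(s2))
        top = als[0]
        assert top.r == pytest.approx(1.0, abs=1e-6)
        assert all(a == b for a, b in top.pairs)
        assert top.n >= 0.9 * len(toy_substructure)
        assert top.ncorr5 == pytest.approx(top.n, rel=1e-4)

    def test_rigid_motion_invariance(self, toy_structure, toy_substructure):
        a1 = slam_align(toy_substructure, structure_as_substructure(rigid_copy(toy_structure, 5)))
        a2 = slam_align(toy_substructure, structure_as_substructure(rigid_copy(toy_structure, 6)))
        assert a1[0].pairs == a2[0].pairs
        assert a1[0].r == pytest.approx(a2[0].r, abs=1e-9)

    def test_ranking_is_stable_across_runs(self, toy_structure, toy_substructure):
        target = structure_as_substructure(rigid_copy(toy_structure, 13))
        r1 = slam_align(toy_substructure, target)
        r2 = slam_align(toy_substructure, target)
        assert [(al.pairs, al.ncorr5) for al in r1] == [(al.pairs, al.ncorr5) for al in r2]

    def test_top_cluster_r_matches_brute_force(self, model):
        """On a small self-screen the emitted correlation equals the optimum
        over all one-to-one sub-matchings of the candidates."""
        rng = np.random.default_rng(17)
        coords = rng.normal(size=(12, 3)) * 4.0
        groups = list(range(1, 7)) * 2
        dabes = [DabeKey(*[int(b) for b in f"{i % 16:04b}"]) for i in range(12)]
        sub_a = make_sub(coords, groups=groups, dabes=dabes, chain="A")
        sub_b = make_sub(coords + 30.0, groups=groups, dabes=dabes, chain="B")
        cfg = SlamConfig()
        als = slam_align(sub_a, sub_b, cfg)
        top = als[0]
        table = accumulate_pair_evidence(sub_a, sub_b, model,
                                         quality_gate_fraction=cfg.quality_gate_fraction)
        cands = select_candidate_pairs(table)[:12]
        ca = {a.atom_id: a.coords for a in sub_a.atoms}
        cb = {b.atom_id: b.coords for b in sub_b.atoms}
        best = -1.0
        for m in range(4, min(len(cands), 8) + 1):
            for subset in combinations(cands, m):
                if len({p[0] for p in subset}) < m or len({p[1] for p in subset}) < m:
                    continue
                try:
                    best = max(best, distance_correlation(subset, ca, cb))
                except DegenerateCorrelationError:
                    continue
        assert top.r == pytest.approx(best, abs=1e-9)
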
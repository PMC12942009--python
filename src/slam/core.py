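"""The spacio-linear alignment engine.

Pipeline (``slam_align``):

1. every heavy atom of each substructure becomes the center of a
   *neighborhood* — its k nearest other atoms serialized as a linear
   sequence sorted by increasing distance from the center;
2. all neighborhood sequences of A are globally aligned against all of B
   (Needleman–Wunsch with affine gaps, atom substitution scores from
   :mod:`slam.annotation`);
3. every atom pair matched in a high-quality alignment accumulates that
   alignment's score as evidence; recurrent pairs separate from background;
4. candidate pairs are merged agglomeratively, a merge being accepted only
   while the Pearson correlation r between the two substructures'
   interatomic-distance vectors stays above ``r_min`` (default 0.85);
5. each emitted 3D alignment is scored Ncorr5 = N·r⁵.

The engine never uses absolute coordinates, only interatomic distances, so
its output is invariant under rigid motion of either substructure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import (
    NEUTRAL_GROUP,
    SubstitutionModel,
    annotate_atoms,
    score_matrix,
)
from .config import SlamConfig
from .errors import DegenerateCorrelationError, ExtractionError
from .structure import AnnotatedAtom, Substructure

__all__ = [
    "Neighborhood",
    "PairAlignment",
    "PairScoreTable",
    "Alignment3D",
    "build_neighborhoods",
    "align_sequences",
    "accumulate_pair_evidence",
    "select_candidate_pairs",
    "distance_correlation",
    "cluster_pairs",
    "ncorr5",
    "slam_align",
]


@dataclass
class Neighborhood:
    """A central atom plus its k nearest heavy atoms, distance-sorted."""

    center: str
    center_index: int
    sequence: list[int]          # indices into the substructure atom list
    sequence_ids: list[str]
    distances: list[float]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairAlignment:
    """One global alignment of two neighborhood sequences."""

    matched_pairs: list[tuple[str, str]]
    score: float
    gaps: int


@dataclass
class PairScoreTable:
    """Cumulative evidence that atom pairs recur in high-quality alignments."""

    evidence: dict[tuple[str, str], float] = field(default_factory=dict)
    n_alignments: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, pair: tuple[str, str], score: float) -> None:
        self.evidence[pair] = self.evidence.get(pair, 0.0) + score
        self.n_alignments[pair] = self.n_alignments.get(pair, 0) + 1

    def __len__(self) -> int:
        return len(self.evidence)


@dataclass
class Alignment3D:
    """A correlation-consistent one-to-one 3D atom matching."""

    pairs: list[tuple[str, str]]
    r: float
    ncorr5: float
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# step 2: neighborhoods
# ---------------------------------------------------------------------------

def build_neighborhoods(sub: Substructure, k: int = 7) -> list[Neighborhood]:
    """One neighborhood per heavy atom; distance ties break by atom id."""
    atoms = sub.atoms
    n = len(atoms)
    if n < k + 1:
        raise ExtractionError(
            f"substructure has {n} atoms; need at least k+1 = {k + 1}"
        )
    coords = sub.coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    ids = [a.atom_id for a in atoms]
    out = []
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (dist[i, j], ids[j]),
        )[:k]
        out.append(
            Neighborhood(
                center=ids[i],
                center_index=i,
                sequence=order,
                sequence_ids=[ids[j] for j in order],
                distances=[float(dist[i, j]) for j in order],
            )
        )
    return out


# ---------------------------------------------------------------------------
# step 4: global alignment with affine gaps (Gotoh)
# ---------------------------------------------------------------------------

_NEG = -1e18


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal global alignment of two sequences given their substitution
    score matrix S (len_a × len_b). A gap run of length L costs
    gap_open + gap_extend·(L−1). Returns (score, pairs, n_gap_runs) with a
    deterministic traceback preferring match > gap-in-B > gap-in-A on ties."""
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A (consumes B)
    pM = np.zeros((la + 1, lb + 1), dtype="U1")
    pX = np.zeros((la + 1, lb + 1), dtype="U1")
    pY = np.zeros((la + 1, lb + 1), dtype="U1")
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        pX[i, 0] = "M" if i == 1 else "X"
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        pY[0, j] = "M" if j == 1 else "Y"

    def _best(options):
        # options: list of (value, state) in preference order; first max wins
        val, st = options[0]
        for v, s in options[1:]:
            if v > val:
                val, st = v, s
        return val, st

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            v, st = _best([(M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"),
                           (Y[i - 1, j - 1], "Y")])
            M[i, j] = S[i - 1, j - 1] + v
            pM[i, j] = st
            v, st = _best([(M[i - 1, j] + gap_open, "M"),
                           (X[i - 1, j] + gap_extend, "X"),
                           (Y[i - 1, j] + gap_open, "Y")])
            X[i, j] = v
            pX[i, j] = st
            v, st = _best([(M[i, j - 1] + gap_open, "M"),
                           (Y[i, j - 1] + gap_extend, "Y"),
                           (X[i, j - 1] + gap_open, "X")])
            Y[i, j] = v
            pY[i, j] = st

    score, state = _best([(M[la, lb], "M"), (X[la, lb], "X"), (Y[la, lb], "Y")])
    pairs: list[tuple[int, int]] = []
    gaps = 0
    i, j = la, lb
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            state_prev = pM[i, j]
            i, j = i - 1, j - 1
        elif state == "X":
            state_prev = pX[i, j]
            if state_prev != "X":
                gaps += 1  # run of gaps begins here
            i -= 1
        else:
            state_prev = pY[i, j]
            if state_prev != "Y":
                gaps += 1
            j -= 1
        state = state_prev
    pairs.reverse()
    return float(score), pairs, gaps


def align_sequences(
    na_atoms: Sequence[AnnotatedAtom],
    nb_atoms: Sequence[AnnotatedAtom],
    m: SubstitutionModel,
    S: np.ndarray | None = None,
) -> PairAlignment:
    """Needleman–Wunsch global alignment of two annotated atom sequences."""
    if S is None:
        S = score_matrix(na_atoms, nb_atoms, m)
    score, idx_pairs, gaps = _gotoh(S, m.gap_open, m.gap_extend)
    matched = [(na_atoms[i].atom_id, nb_atoms[j].atom_id) for i, j in idx_pairs]
    return PairAlignment(matched_pairs=matched, score=score, gaps=gaps)


# ---------------------------------------------------------------------------
# step 5: evidence accumulation and candidate selection
# ---------------------------------------------------------------------------

def _self_scores(atoms: Sequence[AnnotatedAtom], m: SubstitutionModel) -> np.ndarray:
    g = np.array([(a.aa_group or NEUTRAL_GROUP) - 1 for a in atoms])
    diag = m.group_weight_matrix[g, g]
    return diag + m.chem_weight * 4.0


def accumulate_pair_evidence(
    sub_a: Substructure,
    sub_b: Substructure,
    m: SubstitutionModel,
    k: int = 7,
    quality_gate_fraction: float = 0.7,
    include_center_pair: bool = True,
) -> PairScoreTable:
    """All-against-all alignment of A's neighborhoods vs B's.

    An alignment passes the quality gate when its score reaches
    ``quality_gate_fraction`` × the smaller of the two self-alignment
    scores; each of its matched atom pairs (and, by default, the center
    pair itself) then accumulates the alignment score as evidence.
    """
    neigh_a = build_neighborhoods(sub_a, k)
    neigh_b = build_neighborhoods(sub_b, k)
    S = score_matrix(sub_a.atoms, sub_b.atoms, m)
    self_a = _self_scores(sub_a.atoms, m)
    self_b = _self_scores(sub_b.atoms, m)
    self_na = {id(na): float(sum(self_a[j] for j in na.sequence)) for na in neigh_a}
    self_nb = {id(nb): float(sum(self_b[j] for j in nb.sequence)) for nb in neigh_b}

    table = PairScoreTable()
    ids_a = [a.atom_id for a in sub_a.atoms]
    ids_b = [b.atom_id for b in sub_b.atoms]
    go, ge = m.gap_open, m.gap_extend
    for na in neigh_a:
        rows = np.array(na.sequence)
        for nb in neigh_b:
            sub_S = S[np.ix_(rows, np.array(nb.sequence))]
            score, idx_pairs, _ = _gotoh(sub_S, go, ge)
            gate = quality_gate_fraction * min(self_na[id(na)], self_nb[id(nb)])
            if score < gate or score <= 0:
                continue
            for i, j in idx_pairs:
                table.add((ids_a[na.sequence[i]], ids_b[nb.sequence[j]]), score)
            if include_center_pair:
                table.add((na.center, nb.center), score)
    return table


def select_candidate_pairs(
    table: PairScoreTable,
    policy: str = "robust",
    c: float = 2.0,
    quantile: float = 0.05,
    fixed: float | None = None,
    recurrence_min: int = 3,
) -> list[tuple[str, str]]:
    """Separate high-evidence (recurrent) pairs from the background.

    ``robust`` (default): evidence > median + c·1.4826·MAD — a
    scale-robust version of a mean+c·SD outlier cut that still behaves
    sensibly when the background is nearly constant. Pairs matched in at
    least ``recurrence_min`` passing alignments with at-least-median
    evidence are also kept: recurrence across overlapping neighborhoods is
    the primary superimposability signal, and on small clean inputs the
    outlier cut alone would discard a table that is mostly signal.
    ``mean_sd``, ``quantile`` and ``fixed`` are the literal alternatives.
    """
    if not table.evidence:
        return []
    items = sorted(table.evidence.items(), key=lambda kv: (-kv[1], kv[0]))
    values = np.array([v for _, v in items])
    if policy == "robust":
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        threshold = med + c * 1.4826 * mad
        return [
            pair
            for pair, v in items
            if v > threshold
            or (table.n_alignments.get(pair, 0) >= recurrence_min and v >= med)
        ]
    if policy == "mean_sd":
        threshold = values.mean() + c * values.std()
    elif policy == "quantile":
        threshold = float(np.quantile(values, 1.0 - quantile))
    elif policy == "fixed":
        if fixed is None:
            raise ValueError("fixed policy needs a threshold value")
        threshold = float(fixed)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return [pair for pair, v in items if v > threshold]


# ---------------------------------------------------------------------------
# step 6: correlation-constrained agglomerative clustering
# ---------------------------------------------------------------------------

def distance_correlation(
    pairs: Sequence[tuple[str, str]],
    coords_a: dict[str, np.ndarray],
    coords_b: dict[str, np.ndarray],
) -> float:
    """Pearson r between the interatomic-distance vectors of the matched
    atoms in A and in B (all C(N,2) combinations)."""
    if len(pairs) < 3:
        raise DegenerateCorrelationError(f"need ≥3 pairs, got {len(pairs)}")
    pa = np.array([coords_a[a] for a, _ in pairs])
    pb = np.array([coords_b[b] for _, b in pairs])
    da = _pdist(pa)
    db = _pdist(pb)
    if da.std() <= 1e-9 * max(1.0, da.mean()) or db.std() <= 1e-9 * max(1.0, db.mean()):
        raise DegenerateCorrelationError("zero-variance distance vector")
    return float(np.corrcoef(da, db)[0, 1])


def _pdist(points: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(points), k=1)
    diff = points[iu[0]] - points[iu[1]]
    return np.sqrt((diff ** 2).sum(axis=1))


def cluster_pairs(
    candidates: Sequence[tuple[str, str]],
    coords_a: dict[str, np.ndarray],
    coords_b: dict[str, np.ndarray],
    r_min: float = 0.85,
    min_pairs: int = 4,
    bootstrap_tol: float = 1.0,
    expansion_pairs: Sequence[tuple[str, str]] | None = None,
    seed_limit: int = 50,
) -> list[Alignment3D]:
    """Correlation-constrained agglomeration of candidate atom pairs.

    Each of the first ``seed_limit`` candidates (they arrive
    evidence-ranked) seeds a group that greedily accretes, one pair per
    step, the compatible pair whose addition yields the highest
    interatomic-distance correlation of the merged group, as long as that
    correlation exceeds ``r_min`` and the pair reuses no atom on either
    side (one-to-one matching). Accreted pairs are drawn from the
    candidates plus the optional ``expansion_pairs`` pool (every pair ever
    matched in a passing alignment), so a cluster can expand beyond the
    initial high-evidence matches. The very first accretion has a single
    distance component per side, where r is undefined; it is accepted when
    the two distances agree within ``bootstrap_tol`` Å, choosing the best
    agreement.

    A lineage's correlation degrades toward ``r_min`` as weaker pairs join,
    so every growth step is snapshotted and the lineage reports the state
    with the best Ncorr5 (size ≥ ``min_pairs``). Deduplicated snapshots are
    returned ranked by Ncorr5; each is internally one-to-one, but distinct
    alignments may reuse atoms (alternative superimpositions).
    """
    cand = list(dict.fromkeys(candidates))
    if not cand:
        return []
    pool = list(cand)
    seen = set(cand)
    for p in expansion_pairs or ():
        if p not in seen:
            pool.append(p)
            seen.add(p)
    n = len(pool)
    pa = np.array([coords_a[a] for a, _ in pool])
    pb = np.array([coords_b[b] for _, b in pool])

    best_states: dict[frozenset, tuple[float, float, list[int]]] = {}

    for seed_idx in range(min(seed_limit, len(cand))):
        group = [seed_idx]
        used_a = {pool[seed_idx][0]}
        used_b = {pool[seed_idx][1]}
        # per-component running sums of the two distance vectors
        m = 0
        sx = sy = sxx = syy = sxy = 0.0
        compat = np.array(
            [pool[j][0] not in used_a and pool[j][1] not in used_b for j in range(n)]
        )
        best_snapshot: tuple[float, float, list[int]] | None = None
        while compat.any():
            idx = np.where(compat)[0]
            ga = pa[group]  # (u, 3)
            gb = pb[group]
            da = np.sqrt(((pa[idx, None, :] - ga[None, :, :]) ** 2).sum(axis=2))
            db = np.sqrt(((pb[idx, None, :] - gb[None, :, :]) ** 2).sum(axis=2))
            u = len(group)
            if u == 1:
                gap = np.abs(da[:, 0] - db[:, 0])
                ok = (gap <= bootstrap_tol) & (da[:, 0] > 1e-9)
                if not ok.any():
                    break
                j_local = int(np.argmin(np.where(ok, gap, np.inf)))
            else:
                m2 = m + u
                sx2 = sx + da.sum(axis=1)
                sy2 = sy + db.sum(axis=1)
                sxx2 = sxx + (da ** 2).sum(axis=1)
                syy2 = syy + (db ** 2).sum(axis=1)
                sxy2 = sxy + (da * db).sum(axis=1)
                var_x = m2 * sxx2 - sx2 ** 2
                var_y = m2 * syy2 - sy2 ** 2
                denom = np.sqrt(np.clip(var_x * var_y, 0.0, None))
                with np.errstate(invalid="ignore", divide="ignore"):
                    r_all = np.where(denom > 1e-12,
                                     (m2 * sxy2 - sx2 * sy2) / denom, -np.inf)
                ok = r_all > r_min
                if not ok.any():
                    break
                j_local = int(np.argmax(np.where(ok, r_all, -np.inf)))
            j = int(idx[j_local])
            m += u
            sx += float(da[j_local].sum())
            sy += float(db[j_local].sum())
            sxx += float((da[j_local] ** 2).sum())
            syy += float((db[j_local] ** 2).sum())
            sxy += float((da[j_local] * db[j_local]).sum())
            group.append(j)
            used_a.add(pool[j][0])
            used_b.add(pool[j][1])
            compat &= np.array(
                [pool[t][0] not in used_a and pool[t][1] not in used_b for t in range(n)]
            )
            if len(group) >= min_pairs:
                var_x = m * sxx - sx ** 2
                var_y = m * syy - sy ** 2
                denom = np.sqrt(max(var_x * var_y, 0.0))
                if denom > 1e-12:
                    r_now = (m * sxy - sx * sy) / denom
                    score_now = len(group) * r_now ** 5
                    if r_now > r_min and (
                        best_snapshot is None or score_now > best_snapshot[0]
                    ):
                        best_snapshot = (score_now, r_now, list(group))
        if best_snapshot is not None:
            key = frozenset(best_snapshot[2])
            if key not in best_states or best_snapshot[0] > best_states[key][0]:
                best_states[key] = best_snapshot

    out: list[Alignment3D] = []
    for score, r, members in best_states.values():
        pairs = sorted(pool[i] for i in members)
        out.append(
            Alignment3D(
                pairs=pairs,
                r=float(r),
                ncorr5=float(score),
                provenance={"r_min": r_min, "min_pairs": min_pairs},
            )
        )
    out.sort(key=lambda al: (-al.ncorr5, al.pairs))
    return out


# ---------------------------------------------------------------------------
# step 7: scoring and the full pipeline
# ---------------------------------------------------------------------------

def ncorr5(a: Alignment3D) -> float:
    """Alignment score: number of matched pairs times r to the fifth."""
    return a.n * a.r ** 5


def slam_align(
    sub_a: Substructure,
    sub_b: Substructure,
    config: SlamConfig | None = None,
    model: SubstitutionModel | None = None,
) -> list[Alignment3D]:
    """Full spacio-linear alignment of two substructures, Ncorr5-ranked."""
    cfg = config or SlamConfig()
    if model is None:
        model = SubstitutionModel(
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            chem_weight=cfg.chem_weight,
        )
    for sub in (sub_a, sub_b):
        if any(a.dabe is None for a in sub.atoms):
            annotate_atoms(sub.atoms, tolerance=cfg.contact_tolerance)
    table = accumulate_pair_evidence(
        sub_a, sub_b, model,
        k=cfg.k,
        quality_gate_fraction=cfg.quality_gate_fraction,
        include_center_pair=cfg.include_center_pair,
    )
    candidates = select_candidate_pairs(
        table,
        policy=cfg.candidate_policy,
        c=cfg.candidate_c,
        quantile=cfg.candidate_quantile,
        fixed=cfg.candidate_fixed,
    )
    coords_a = {a.atom_id: a.coords for a in sub_a.atoms}
    coords_b = {b.atom_id: b.coords for b in sub_b.atoms}
    pool = [
        pair
        for pair, _ in sorted(table.evidence.items(), key=lambda kv: (-kv[1], kv[0]))
    ][: cfg.expansion_pool_limit]
    alignments = cluster_pairs(
        candidates, coords_a, coords_b,
        r_min=cfg.r_min,
        min_pairs=cfg.min_cluster_pairs,
        bootstrap_tol=cfg.bootstrap_distance_tol,
        expansion_pairs=pool,
        seed_limit=cfg.cluster_seed_limit,
    )
    for al in alignments:
        al.provenance.update(
            {"k": cfg.k, "candidate_policy": cfg.candidate_policy,
             "quality_gate_fraction": cfg.quality_gate_fraction}
        )
    return alignments
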
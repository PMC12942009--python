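"""Physicochemical atom annotation.

Every heavy atom gets a 4-bit DABE key — hydrogen-bond Donor, Acceptor,
Bulkiness, Electropositivity — plus a reduced-alphabet amino-acid group, and
the module defines the atom-to-atom substitution score used by the sequence
aligner: the scaled amino-acid group weight plus the number of shared DABE
properties (0–4).

Bulkiness and electropositivity depend on the atom's van der Waals contact
neighborhood and therefore on conformation; :func:`annotate_structure` must
be re-run if coordinates change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (
    STANDARD_RESIDUES,
    electronegativity,
    hbond_templates,
)
from .errors import AnnotationError
from .structure import AnnotatedAtom, Structure

logger = logging.getLogger(__name__)

#: strict volume threshold (Å³) of the bulkiness criterion
BULKINESS_VOLUME_CUTOFF = 10.0
#: electronegativity ceiling for the electropositivity bit
ELECTROPOSITIVITY_CUTOFF = 2.5

#: reduced seven-group amino-acid alphabet; group 7 is the neutral
#: "other/unknown" class used for hetero atoms inside a patch
AA_GROUPS: dict[str, int] = {
    **dict.fromkeys(["ALA", "GLY", "PRO", "SER", "THR"], 1),
    "CYS": 2,
    **dict.fromkeys(["ASP", "GLU", "ASN", "GLN"], 3),
    **dict.fromkeys(["PHE", "TRP", "TYR"], 4),
    **dict.fromkeys(["HIS", "LYS", "ARG"], 5),
    **dict.fromkeys(["ILE", "LEU", "MET", "VAL"], 6),
    "MSE": 6,  # selenomethionine behaves as methionine
}
NEUTRAL_GROUP = 7

_GROUP_MEMBERS = {
    1: "AGPST",
    2: "C",
    3: "DENQ",
    4: "FWY",
    5: "HKR",
    6: "ILMV",
}


@dataclass(frozen=True)
class DabeKey:
    """Four-bit physicochemical key in D, A, B, E order."""

    donor: int
    acceptor: int
    bulky: int
    electropositive: int

    def __post_init__(self) -> None:
        for bit in self.bits:
            if bit not in (0, 1):
                raise ValueError(f"DABE bits must be 0/1, got {self.bits}")

    @property
    def bits(self) -> tuple[int, int, int, int]:
        return (self.donor, self.acceptor, self.bulky, self.electropositive)

    def as_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "DabeKey":
        return cls(*(int(b) for b in bits))


def dabe_similarity(k1: DabeKey, k2: DabeKey) -> int:
    """Number of shared DABE properties: 4 minus the Hamming distance."""
    return sum(int(b1 == b2) for b1, b2 in zip(k1.bits, k2.bits))


# ---------------------------------------------------------------------------
# per-atom property computation
# ---------------------------------------------------------------------------

def contact_neighbors(
    a: AnnotatedAtom,
    atoms: Iterable[AnnotatedAtom],
    tolerance: float = 0.0,
) -> list[AnnotatedAtom]:
    """Heavy atoms j ≠ a with dist(a, j) ≤ w_a + w_j + tolerance."""
    out = []
    for j in atoms:
        if j is a or not j.is_heavy:
            continue
        if np.linalg.norm(a.coords - j.coords) <= a.vdw_radius + j.vdw_radius + tolerance:
            out.append(j)
    return out


def compute_bulkiness(a: AnnotatedAtom, neighbors: Iterable[AnnotatedAtom]) -> int:
    """1 iff w_a³ + Σ_j w_j³ strictly exceeds 10 Å³."""
    if a.vdw_radius <= 0:
        raise AnnotationError(f"{a.atom_id}: missing van der Waals radius")
    volume = a.vdw_radius ** 3
    for j in neighbors:
        if j.vdw_radius <= 0:
            raise AnnotationError(f"{j.atom_id}: missing van der Waals radius")
        volume += j.vdw_radius ** 3
    return int(volume > BULKINESS_VOLUME_CUTOFF)


def compute_electropositivity(
    a: AnnotatedAtom, neighbors: Iterable[AnnotatedAtom]
) -> int:
    """1 iff the atom's and all its contact neighbors' Pauling
    electronegativities are ≤ 2.5."""
    if electronegativity(a.element) > ELECTROPOSITIVITY_CUTOFF:
        return 0
    for j in neighbors:
        if electronegativity(j.element) > ELECTROPOSITIVITY_CUTOFF:
            return 0
    return 1


def assign_hbond_flags(a: AnnotatedAtom) -> tuple[int, int]:
    """(donor, acceptor) flags from the bundled residue/atom template table,
    falling back to an element heuristic for unknown names."""
    t = hbond_templates()
    resname = a.residue_name.upper()
    name = a.name.upper()
    res_table = t["residues"].get(resname)
    if res_table is not None:
        if name in res_table:
            return res_table[name]
        if name in t["backbone"]:
            return t["backbone"][name]
        return (0, 0)
    if resname in STANDARD_RESIDUES and name in t["backbone"]:
        return t["backbone"][name]
    fallback = t["element_fallback"].get(a.element.upper())
    if fallback is not None:
        logger.warning(
            "no donor/acceptor template for %s %s; element fallback used",
            resname, name,
        )
        return fallback
    return (0, 0)


def dabe_key(
    a: AnnotatedAtom,
    context_atoms: Iterable[AnnotatedAtom],
    tolerance: float = 0.0,
) -> DabeKey:
    """Compose the DABE key of *a* inside the given structural context."""
    neighbors = contact_neighbors(a, context_atoms, tolerance)
    donor, acceptor = assign_hbond_flags(a)
    return DabeKey(
        donor=donor,
        acceptor=acceptor,
        bulky=compute_bulkiness(a, neighbors),
        electropositive=compute_electropositivity(a, neighbors),
    )


def annotate_atoms(
    atoms: Sequence[AnnotatedAtom], tolerance: float = 0.0
) -> None:
    """Annotate every heavy atom in *atoms* in place (DABE key + aa group).

    Uses a KD-tree over the whole atom set so that bulkiness and
    electropositivity see the full structural context.
    """
    heavy = [a for a in atoms if a.is_heavy]
    if not heavy:
        return
    coords = np.array([a.coords for a in heavy])
    radii = np.array([a.vdw_radius for a in heavy])
    tree = cKDTree(coords)
    max_contact = 2.0 * radii.max() + tolerance
    for i, a in enumerate(heavy):
        idx = tree.query_ball_point(coords[i], r=max_contact)
        neighbors = [
            heavy[j]
            for j in idx
            if j != i
            and np.linalg.norm(coords[i] - coords[j]) <= radii[i] + radii[j] + tolerance
        ]
        donor, acceptor = assign_hbond_flags(a)
        a.dabe = DabeKey(
            donor=donor,
            acceptor=acceptor,
            bulky=compute_bulkiness(a, neighbors),
            electropositive=compute_electropositivity(a, neighbors),
        )
        a.aa_group = AA_GROUPS.get(a.residue_name.upper(), NEUTRAL_GROUP)


def annotate_structure(s: Structure, tolerance: float = 0.0) -> Structure:
    """Annotate all heavy atoms of *s* (polymer and ligands) in place."""
    all_atoms = list(s.atoms())
    for lig in s.ligands:
        all_atoms.extend(lig.atoms)
    annotate_atoms(all_atoms, tolerance)
    return s


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _pam250_group_matrix() -> np.ndarray:
    """7×7 group weight matrix: PAM250 entries averaged within group pairs,
    affinely rescaled so the 6 real groups span [0, 4].

    The neutral group 7 (hetero/unknown atoms) scores half the smallest
    real self-weight against every real group and the smallest real
    self-weight against itself, keeping every row diagonally dominant so a
    neutral atom never outranks a same-group match."""
    from Bio.Align import substitution_matrices

    pam = substitution_matrices.load("PAM250")
    raw = np.zeros((6, 6))
    for g1, m1 in _GROUP_MEMBERS.items():
        for g2, m2 in _GROUP_MEMBERS.items():
            vals = [pam[a, b] for a in m1 for b in m2]
            raw[g1 - 1, g2 - 1] = float(np.mean(vals))
    lo, hi = raw.min(), raw.max()
    scaled = (raw - lo) / (hi - lo) * 4.0
    d_min = scaled.diagonal().min()
    full = np.full((7, 7), d_min / 2.0)
    full[:6, :6] = scaled
    full[6, 6] = d_min
    return full


@dataclass
class SubstitutionModel:
    """Scoring model for atom-sequence alignment.

    ``group_weight_matrix`` is symmetric, scaled to [0, 4] to match the DABE
    similarity range; gap penalties are affine (a length-L gap run costs
    ``gap_open + gap_extend·(L−1)``).
    """

    aa_group_map: dict[str, int] = field(default_factory=lambda: dict(AA_GROUPS))
    group_weight_matrix: np.ndarray = field(default_factory=_pam250_group_matrix)
    gap_open: float = -4.0
    gap_extend: float = -1.0
    chem_weight: float = 1.0

    def group_weight(self, g1: int | None, g2: int | None) -> float:
        i = (g1 or NEUTRAL_GROUP) - 1
        j = (g2 or NEUTRAL_GROUP) - 1
        return float(self.group_weight_matrix[i, j])

    @classmethod
    def default(cls) -> "SubstitutionModel":
        return cls()


def atom_substitution_score(
    a: AnnotatedAtom, b: AnnotatedAtom, m: SubstitutionModel
) -> float:
    """Amino-acid group weight plus weighted DABE similarity; symmetric."""
    if a.dabe is None or b.dabe is None:
        raise AnnotationError("atoms must be annotated before scoring")
    return m.group_weight(a.aa_group, b.aa_group) + m.chem_weight * dabe_similarity(
        a.dabe, b.dabe
    )


def score_matrix(
    atoms_a: Sequence[AnnotatedAtom],
    atoms_b: Sequence[AnnotatedAtom],
    m: SubstitutionModel,
) -> np.ndarray:
    """Vectorized |A|×|B| table of atom substitution scores."""
    ga = np.array([(a.aa_group or NEUTRAL_GROUP) - 1 for a in atoms_a])
    gb = np.array([(b.aa_group or NEUTRAL_GROUP) - 1 for b in atoms_b])
    for a in list(atoms_a) + list(atoms_b):
        if a.dabe is None:
            raise AnnotationError(f"{a.atom_id}: not annotated")
    bits_a = np.array([a.dabe.bits for a in atoms_a])
    bits_b = np.array([b.dabe.bits for b in atoms_b])
    shared = (bits_a[:, None, :] == bits_b[None, :, :]).sum(axis=2)
    return m.group_weight_matrix[np.ix_(ga, gb)] + m.chem_weight * shared
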
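"""Deterministic synthetic structures with known ground truth.

These generators make the whole pipeline testable without downloading any
real structure: a self-avoiding chain of idealized residues, a pair of
hosts sharing a planted (optionally chemistry-shuffled) motif with a known
atom-pair mapping, and a protein–ligand toy complex with a guaranteed
pocket residue count. Geometry is idealized (fixed local templates, no
torsional realism) — the aligner only consumes interatomic distances and
chemistry, so conformational realism is deliberately out of scope.

All outputs are pure functions of their arguments, seed included.
"""

from __future__ import annotations

import numpy as np

from .errors import GenerationError
from .structure import AnnotatedAtom, Ligand, Residue, Structure

# side-chain heavy atoms per residue type (canonical PDB names)
_SIDE_CHAINS: dict[str, list[str]] = {
    "GLY": [],
    "ALA": ["CB"],
    "SER": ["CB", "OG"],
    "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1", "CG2"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PRO": ["CB", "CG", "CD"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
}

_BACKBONE = {
    "N": np.array([-1.458, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.55, 1.40, 0.0]),
    "O": np.array([0.64, 2.62, 0.15]),
}
_CB_LOCAL = np.array([0.54, -0.78, -1.21])

MIN_SEPARATION = 1.2  # Å, enforced between all atoms of a generated structure


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from {atom_name!r}")


def residue_template(resname: str) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, local coords) for every heavy atom of *resname*.

    Side chains extend from CB along a fixed helical path — idealized but
    collision-free internal geometry.
    """
    atoms = [(n, _element_of(n), p.copy()) for n, p in _BACKBONE.items()]
    side = _SIDE_CHAINS[resname]
    if not side:
        return atoms
    atoms.append(("CB", "C", _CB_LOCAL.copy()))
    u = _CB_LOCAL / np.linalg.norm(_CB_LOCAL)
    v = np.cross(u, np.array([0.0, 0.0, 1.0]))
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    for i, name in enumerate(side[1:]):
        pos = (
            _CB_LOCAL
            + 1.3 * (i + 1) * u
            + 0.55 * np.cos(2.2 * i) * v
            + 0.55 * np.sin(2.2 * i) * w
        )
        atoms.append((name, _element_of(name), pos))
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    a, b, c, d = q
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )


def make_random_structure(
    n_residues: int,
    seed: int,
    resnames: list[str] | None = None,
    structure_id: str | None = None,
    max_attempts: int = 400,
) -> Structure:
    """Self-avoiding chain of *n_residues* idealized residues (~8 heavy
    atoms each), minimum interatomic separation 1.2 Å, chain id 'A'."""
    if n_residues < 1:
        raise GenerationError("n_residues must be ≥ 1")
    rng = np.random.default_rng(seed)
    pool = resnames or sorted(_SIDE_CHAINS)
    chosen = [pool[int(i)] for i in rng.integers(0, len(pool), size=n_residues)]
    s = Structure(structure_id or f"synth{seed}")
    accepted_coords: list[np.ndarray] = []
    ca_positions: list[np.ndarray] = []
    for ridx, resname in enumerate(chosen, start=1):
        template = residue_template(resname)
        placed = False
        for _ in range(max_attempts):
            if not ca_positions:
                ca = np.zeros(3)
            else:
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                ca = ca_positions[-1] + step
                if len(ca_positions) > 1:
                    prev = np.array(ca_positions[:-1])
                    if (np.linalg.norm(prev - ca, axis=1) < 4.2).any():
                        continue
            R = _random_rotation(rng)
            coords = np.array([ca + R @ p for _, _, p in template])
            if accepted_coords:
                prev_atoms = np.vstack(accepted_coords)
                d = np.linalg.norm(
                    prev_atoms[:, None, :] - coords[None, :, :], axis=2
                )
                if (d < MIN_SEPARATION).any():
                    continue
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place residue {ridx} after {max_attempts} attempts"
            )
        ca_positions.append(ca)
        accepted_coords.append(coords)
        res = Residue("A", resname, ridx)
        for (name, element, _), coord in zip(template, coords):
            res.atoms.append(
                AnnotatedAtom(
                    atom_id=f"A:{ridx}:{name}",
                    name=name,
                    element=element,
                    coords=coord,
                    chain_id="A",
                    residue_name=resname,
                    residue_seq=ridx,
                )
            )
        s.add_residue(res)
    return s


def plant_shared_motif(
    host_a: Structure,
    host_b: Structure,
    motif_size: int,
    jitter_sigma: float,
    seed: int,
    shuffle_chemistry: bool = False,
    max_attempts: int = 50,
):
    """Copy a contiguous *motif_size*-atom substructure of A into B under a
    random rigid transform plus per-atom Gaussian jitter.

    Residue identities (hence chemistry) are preserved, so the planted
    atoms are recoverable; with ``shuffle_chemistry`` the copied atoms'
    chemical labels (residue, name, element) are permuted while the
    geometry stays, producing a same-shape decoy. Returns
    ``(host_a, new_host_b, ground_truth_pairs)``.
    """
    atoms_a = [a for a in host_a.atoms() if a.is_heavy]
    if motif_size > len(atoms_a):
        raise GenerationError(
            f"motif_size {motif_size} exceeds host atoms {len(atoms_a)}"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(atoms_a) - motif_size + 1))
    motif = atoms_a[start : start + motif_size]
    motif_coords = np.array([a.coords for a in motif])

    host_atoms = np.array([a.coords for a in host_b.atoms() if a.is_heavy])
    center_b = host_atoms.mean(axis=0)
    radius_b = np.linalg.norm(host_atoms - center_b, axis=1).max()
    center_m = motif_coords.mean(axis=0)
    radius_m = np.linalg.norm(motif_coords - center_m, axis=1).max()

    new_b = host_b.copy()
    placed_coords = None
    for attempt in range(max_attempts):
        R = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        gap = 3.0 + 0.5 * attempt
        target_center = center_b + direction * (radius_b + radius_m + gap)
        coords = (motif_coords - center_m) @ R.T + target_center
        coords = coords + rng.normal(0.0, jitter_sigma, size=coords.shape)
        d = np.linalg.norm(host_atoms[:, None, :] - coords[None, :, :], axis=2)
        if d.min() >= 2.0:
            placed_coords = coords
            break
    if placed_coords is None:
        raise GenerationError("could not place motif without clashes")

    # chemistry labels: identity or a seeded permutation (decoy mode)
    perm = rng.permutation(motif_size) if shuffle_chemistry else np.arange(motif_size)

    ground_truth = []
    current_res: Residue | None = None
    current_key = None
    used_ids: set[str] = set()
    for i, (src, coord) in enumerate(zip(motif, placed_coords)):
        label = motif[perm[i]]
        key = (src.residue_seq, src.insertion_code, label.residue_name if shuffle_chemistry else src.residue_name)
        if current_res is None or key != current_key:
            current_res = Residue("M", key[2], src.residue_seq, src.insertion_code)
            new_b.add_residue(current_res)
            current_key = key
        atom_id = f"M:{src.residue_seq}{src.insertion_code}:{label.name}"
        while atom_id in used_ids:
            atom_id += "'"
        used_ids.add(atom_id)
        atom = AnnotatedAtom(
            atom_id=atom_id,
            name=label.name,
            element=label.element,
            coords=coord,
            chain_id="M",
            residue_name=key[2],
            residue_seq=src.residue_seq,
            insertion_code=src.insertion_code,
        )
        current_res.atoms.append(atom)
        ground_truth.append((src.atom_id, atom_id))
    return host_a, new_b, ground_truth


def make_toy_complex(
    pocket_residues: int,
    ligand_atoms: int,
    seed: int,
    n_extra_residues: int = 4,
) -> Structure:
    """Random structure plus a small ligand positioned so that exactly
    *pocket_residues* residues have a heavy atom within 7 Å of it."""
    if ligand_atoms < 3:
        raise GenerationError("ligand_atoms must be ≥ 3")
    rng = np.random.default_rng(seed)
    n_res = pocket_residues + n_extra_residues
    s = make_random_structure(n_res, seed=int(rng.integers(0, 2**31 - 1)))

    lig_local = np.array(
        [
            [1.5 * np.cos(2.0 * i), 1.5 * np.sin(2.0 * i), 0.35 * i]
            for i in range(ligand_atoms)
        ]
    )
    lig_local -= lig_local.mean(axis=0)
    elements = [("C", "N", "O")[i % 3] for i in range(ligand_atoms)]

    residues = list(s.residues())
    protein_coords = np.array([a.coords for a in s.atoms()])
    centroid = protein_coords.mean(axis=0)

    def pocket_count(lig_coords: np.ndarray) -> int:
        count = 0
        for res in residues:
            coords = np.array([a.coords for a in res.heavy_atoms()])
            d = np.linalg.norm(
                coords[:, None, :] - lig_coords[None, :, :], axis=2
            )
            if (d <= 7.0).any():
                count += 1
        return count

    candidate_dirs = []
    for res in residues:
        base = np.array([a.coords for a in res.heavy_atoms()]).mean(axis=0)
        radial = base - centroid
        nrm = np.linalg.norm(radial)
        radial = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        candidate_dirs.append((base, radial))
        for _ in range(8):
            u = rng.normal(size=3)
            candidate_dirs.append((base, u / np.linalg.norm(u)))
    for base, direction in candidate_dirs:
        for t in np.linspace(0.0, 15.0, 151):
            lig_coords = lig_local + base + direction * t
            d_all = np.linalg.norm(
                protein_coords[:, None, :] - lig_coords[None, :, :], axis=2
            )
            # keep the ligand at van der Waals contact distance, not overlapping
            if d_all.min() < 3.5:
                continue
            if pocket_count(lig_coords) == pocket_residues:
                ligand = Ligand("LIG", "L", 1)
                for i, (coord, el) in enumerate(zip(lig_coords, elements), start=1):
                    ligand.atoms.append(
                        AnnotatedAtom(
                            atom_id=f"L:1:L{i}",
                            name=f"L{i}",
                            element=el,
                            coords=coord,
                            chain_id="L",
                            residue_name="LIG",
                            residue_seq=1,
                            is_hetero=True,
                        )
                    )
                s.add_ligand(ligand)
                return s
    raise GenerationError(
        f"no ligand placement with exactly {pocket_residues} pocket residues"
    )
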
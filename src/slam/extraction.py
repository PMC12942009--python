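"""Substructure extraction: ligand-binding cavities and solvent-exposed
surface patches, the two reference inputs the aligner screens against.

A cavity is the set of whole residues with at least one heavy atom within
7 Å of any ligand heavy atom, kept only if it has ≥ 40 atoms. A surface
patch is the analogous 7 Å residue shell around a single solvent-exposed
atom (SASA > 2 Å², Shrake–Rupley with a 1.4 Å probe). SASA is computed per
isolated chain; ligands and other chains do not occlude by default.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LookupError_
from .structure import (
    Ligand,
    Structure,
    Substructure,
    substructure_to_structure,
    write_structure,
)

logger = logging.getLogger(__name__)


def _residue_shell(
    s: Structure,
    reference_coords: np.ndarray,
    radius: float,
    chain_id: str | None = None,
) -> list:
    """Whole residues of *s* with ≥1 heavy atom within *radius* of any
    reference point."""
    if radius <= 0 or len(reference_coords) == 0:
        return []
    selected = []
    for res in s.residues(chain_id):
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        coords = np.array([a.coords for a in heavy])
        d = np.linalg.norm(coords[:, None, :] - reference_coords[None, :, :], axis=2)
        if (d <= radius).any():
            selected.append(res)
    return selected


def extract_ligand_cavity(
    s: Structure,
    ligand: Ligand,
    radius: float = 7.0,
    min_atoms: int = 40,
    chain_id: str | None = None,
) -> Substructure | None:
    """Residue shell around a bound ligand, or None if below *min_atoms*.

    The ligand's own atoms are never part of the cavity.
    """
    lig_coords = np.array([a.coords for a in ligand.atoms if a.is_heavy])
    if len(lig_coords) == 0:
        return None
    residues = _residue_shell(s, lig_coords, radius, chain_id)
    atoms = [a for res in residues for a in res.heavy_atoms()]
    if len(atoms) < min_atoms:
        return None
    return Substructure(
        structure_id=s.structure_id,
        chain_id=chain_id or "*",
        role="ligand_cavity",
        atoms=atoms,
        anchor=ligand.ligand_id,
    )


def compute_sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    chain_id: str | None = None,
) -> dict[str, float]:
    """Per-atom Shrake–Rupley solvent-accessible surface areas (Å²).

    Only the selected chain's heavy polymer atoms form the occlusion
    environment; areas are returned keyed by atom id.
    """
    import biotite.structure as struc

    atoms = [a for a in s.atoms(chain_id) if a.is_heavy]
    if not atoms:
        return {}
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    for i, a in enumerate(atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_seq
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
    radii = np.array([a.vdw_radius for a in atoms])
    areas = struc.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    out: dict[str, float] = {}
    for a, area in zip(atoms, areas):
        val = float(area) if np.isfinite(area) else 0.0
        a.sasa = val
        out[a.atom_id] = val
    return out


def surface_atoms(areas: dict[str, float], threshold: float = 2.0) -> list[str]:
    """Atom ids with strictly more than *threshold* Å² of exposed area."""
    return [atom_id for atom_id, area in areas.items() if area > threshold]


def extract_surface_patch(
    s: Structure,
    center_atom_id: str,
    radius: float = 7.0,
) -> Substructure:
    """Whole-residue 7 Å shell around one surface-exposed atom."""
    center = s.get_atom(center_atom_id)  # raises LookupError_ if absent
    residues = _residue_shell(s, center.coords[None, :], radius)
    atoms = [a for res in residues for a in res.heavy_atoms()]
    return Substructure(
        structure_id=s.structure_id,
        chain_id=center.chain_id,
        role="surface_patch",
        atoms=atoms,
        anchor=center_atom_id,
    )


def build_patch_database(
    structures: Iterable[Structure],
    out_dir: str | Path,
    radius: float = 7.0,
    probe: float = 1.4,
    n_points: int = 960,
    sasa_min_area: float = 2.0,
    dedup_residue_sets: bool = False,
) -> pd.DataFrame:
    """One surface patch per solvent-exposed atom of every chain.

    Writes a PDB fragment per patch plus a TSV manifest
    (structure_id, chain, role, anchor, n_atoms, path); rerunning over the
    same inputs reproduces the manifest byte-identically. Per-structure
    failures are logged and skipped, not fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in structures:
        try:
            for chain_id in s.chains:
                areas = compute_sasa(s, probe=probe, n_points=n_points, chain_id=chain_id)
                exposed = surface_atoms(areas, threshold=sasa_min_area)
                if not exposed:
                    logger.info("%s chain %s: no surface-exposed atoms", s.structure_id, chain_id)
                seen_residue_sets: set[frozenset] = set()
                for idx, atom_id in enumerate(exposed):
                    patch = extract_surface_patch(s, atom_id, radius=radius)
                    if dedup_residue_sets:
                        key = frozenset(patch.residue_keys())
                        if key in seen_residue_sets:
                            continue
                        seen_residue_sets.add(key)
                    fname = f"{s.structure_id}_{chain_id}_patch{idx:05d}.pdb"
                    write_structure(substructure_to_structure(patch), out_dir / fname)
                    rows.append(
                        {
                            "structure_id": s.structure_id,
                            "chain": chain_id,
                            "role": "surface_patch",
                            "anchor": atom_id,
                            "n_atoms": len(patch),
                            "path": fname,
                        }
                    )
        except LookupError_ as exc:
            logger.error("%s: %s", s.structure_id, exc)
    manifest = pd.DataFrame(
        rows, columns=["structure_id", "chain", "role", "anchor", "n_atoms", "path"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def build_cavity_database(
    structures: Iterable[Structure],
    out_dir: str | Path,
    radius: float = 7.0,
    min_atoms: int = 40,
) -> pd.DataFrame:
    """Per-chain ligand cavities for every ligand of every structure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in structures:
        for lig in s.ligands:
            for chain_id in s.chains:
                cavity = extract_ligand_cavity(
                    s, lig, radius=radius, min_atoms=min_atoms, chain_id=chain_id
                )
                if cavity is None:
                    continue
                fname = f"{s.structure_id}_{chain_id}_{lig.ligand_id}_cavity.pdb"
                write_structure(substructure_to_structure(cavity), out_dir / fname)
                rows.append(
                    {
                        "structure_id": s.structure_id,
                        "chain": chain_id,
                        "role": "ligand_cavity",
                        "anchor": lig.ligand_id,
                        "n_atoms": len(cavity),
                        "path": fname,
                    }
                )
    manifest = pd.DataFrame(
        rows, columns=["structure_id", "chain", "role", "anchor", "n_atoms", "path"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
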
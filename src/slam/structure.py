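"""Structure model: PDB/mmCIF reading and writing, heavy-atom access and the
substructure container every other module operates on.

A :class:`Structure` holds ordered chains of ordered residues of
:class:`AnnotatedAtom`; HETATM groups that are neither water nor whitelisted
modified residues become :class:`Ligand` objects. Only the first model of a
multi-model file is read and, per altloc group, only the highest-occupancy
conformer (ties broken toward altloc 'A') is kept — all downstream geometry
assumes a single conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.PDB import MMCIFParser, PDBParser

from ._tables import (
    MODIFIED_RESIDUE_WHITELIST,
    STANDARD_RESIDUES,
    WATER_NAMES,
    vdw_radii,
    vdw_radius,
)
from .errors import AnnotationError, LookupError_, StructureFormatError

_HYDROGEN = {"H", "D"}


@dataclass
class AnnotatedAtom:
    """A single atom with residue context and (lazily filled) annotations.

    ``dabe``, ``aa_group`` and ``sasa`` start unset and are populated by
    :mod:`slam.annotation` and :mod:`slam.extraction`.
    """

    atom_id: str
    name: str
    element: str
    coords: np.ndarray
    chain_id: str
    residue_name: str
    residue_seq: int
    insertion_code: str = ""
    vdw_radius: float = 0.0
    is_heavy: bool = True
    is_hetero: bool = False
    dabe: Optional["object"] = None
    aa_group: Optional[int] = None
    sasa: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.element = self.element.upper()
        self.is_heavy = self.element not in _HYDROGEN
        if self.is_heavy and self.vdw_radius <= 0.0:
            self.vdw_radius = vdw_radius(self.element)
        elif not self.is_heavy and self.vdw_radius <= 0.0:
            self.vdw_radius = vdw_radii().get(self.element, 1.20)

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_seq, self.insertion_code, self.residue_name)

    def copy(self) -> "AnnotatedAtom":
        new = AnnotatedAtom(
            atom_id=self.atom_id,
            name=self.name,
            element=self.element,
            coords=self.coords.copy(),
            chain_id=self.chain_id,
            residue_name=self.residue_name,
            residue_seq=self.residue_seq,
            insertion_code=self.insertion_code,
            vdw_radius=self.vdw_radius,
            is_hetero=self.is_hetero,
        )
        new.dabe = self.dabe
        new.aa_group = self.aa_group
        new.sasa = self.sasa
        return new


@dataclass
class Residue:
    chain_id: str
    name: str
    seq: int
    insertion_code: str = ""
    atoms: list[AnnotatedAtom] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq, self.insertion_code, self.name)

    def heavy_atoms(self) -> list[AnnotatedAtom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class Ligand:
    """A non-water, non-polymer HETATM group. Heavy atoms only."""

    ligand_id: str
    chain_id: str
    residue_seq: int
    atoms: list[AnnotatedAtom] = field(default_factory=list)


class Structure:
    """Ordered chains of residues plus ligands; deterministic iteration."""

    def __init__(self, structure_id: str):
        self.structure_id = structure_id
        self.chains: dict[str, list[Residue]] = {}
        self.ligands: list[Ligand] = []

    # -- construction -----------------------------------------------------
    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)

    def add_ligand(self, ligand: Ligand) -> None:
        self.ligands.append(ligand)

    # -- access -----------------------------------------------------------
    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is None:
            for residues in self.chains.values():
                yield from residues
        else:
            if chain_id not in self.chains:
                raise LookupError_(f"no chain {chain_id!r} in {self.structure_id}")
            yield from self.chains[chain_id]

    def atoms(self, chain_id: str | None = None) -> Iterator[AnnotatedAtom]:
        for res in self.residues(chain_id):
            yield from res.atoms

    def atom_map(self) -> dict[str, AnnotatedAtom]:
        m: dict[str, AnnotatedAtom] = {}
        for a in self.atoms():
            m[a.atom_id] = a
        for lig in self.ligands:
            for a in lig.atoms:
                m[a.atom_id] = a
        return m

    def get_atom(self, atom_id: str) -> AnnotatedAtom:
        try:
            return self.atom_map()[atom_id]
        except KeyError:
            raise LookupError_(f"no atom {atom_id!r} in {self.structure_id}") from None

    def copy(self) -> "Structure":
        new = Structure(self.structure_id)
        for chain_id, residues in self.chains.items():
            for res in residues:
                new.add_residue(
                    Residue(chain_id, res.name, res.seq, res.insertion_code,
                            [a.copy() for a in res.atoms])
                )
        for lig in self.ligands:
            new.add_ligand(Ligand(lig.ligand_id, lig.chain_id, lig.residue_seq,
                                  [a.copy() for a in lig.atoms]))
        return new


def heavy_atoms(s: Structure, chain_id: str | None = None) -> list[AnnotatedAtom]:
    """All heavy (non-hydrogen, non-deuterium) polymer atoms, file order."""
    return [a for a in s.atoms(chain_id) if a.is_heavy]


@dataclass
class Substructure:
    """The unit the aligner compares: a ligand cavity or a surface patch.

    Atoms are ordered deterministically by (chain, residue number, insertion
    code, atom name); a cavity is anchored on its ligand id, a patch on its
    central atom id.
    """

    structure_id: str
    chain_id: str
    role: str  # "ligand_cavity" | "surface_patch"
    atoms: list[AnnotatedAtom]
    anchor: str

    def __post_init__(self) -> None:
        self.atoms = sorted(
            self.atoms,
            key=lambda a: (a.chain_id, a.residue_seq, a.insertion_code, a.name),
        )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def atom_ids(self) -> list[str]:
        return [a.atom_id for a in self.atoms]

    def residue_keys(self) -> set[tuple]:
        return {a.residue_key for a in self.atoms}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _make_atom_id(chain_id: str, seq: int, icode: str, name: str) -> str:
    return f"{chain_id}:{seq}{icode}:{name}"


def _pick_altloc(atom, policy: str):
    """Resolve a possibly disordered Biopython atom to one conformer."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    if policy == "first":
        return children[0]
    # occupancy policy: highest occupancy, ties toward altloc 'A'
    return sorted(children, key=lambda c: (-(c.get_occupancy() or 0.0), c.get_altloc()))[0]


def read_structure(
    path: str | Path,
    altloc_policy: str = "occupancy",
    modified_residues: Iterable[str] = MODIFIED_RESIDUE_WHITELIST,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB or PDBx/mmCIF file into a :class:`Structure`.

    HETATM residues are partitioned into ligands (non-water, non-standard,
    not in *modified_residues*) and polymer residues; the first model is
    used; hydrogens are kept but flagged non-heavy.
    """
    path = Path(path)
    if structure_id is None:
        structure_id = path.stem
    parser = (
        MMCIFParser(QUIET=True)
        if path.suffix.lower() in {".cif", ".mmcif"}
        else PDBParser(QUIET=True)
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(structure_id, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise StructureFormatError(f"{path}: no model found")
    model = models[0]

    modified = {m.upper() for m in modified_residues}
    out = Structure(structure_id)
    n_atoms = 0
    for chain in model:
        chain_id = chain.id.strip() or "A"
        for residue in chain:
            hetflag, seq, icode = residue.id
            icode = icode.strip()
            resname = residue.get_resname().strip().upper()
            is_water = resname in WATER_NAMES or hetflag == "W"
            is_het = hetflag.strip() != ""
            atoms: list[AnnotatedAtom] = []
            seen: set[str] = set()
            for raw in residue:
                atom = _pick_altloc(raw, altloc_policy)
                name = atom.get_name().strip()
                if name in seen:
                    continue
                seen.add(name)
                element = (atom.element or "").strip().upper() or name[0]
                try:
                    a = AnnotatedAtom(
                        atom_id=_make_atom_id(chain_id, seq, icode, name),
                        name=name,
                        element=element,
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        chain_id=chain_id,
                        residue_name=resname,
                        residue_seq=seq,
                        insertion_code=icode,
                        is_hetero=is_het,
                    )
                except AnnotationError:
                    raise
                atoms.append(a)
                n_atoms += 1
            if not atoms:
                continue
            if is_water:
                continue
            if is_het and resname not in STANDARD_RESIDUES and resname not in modified:
                out.add_ligand(
                    Ligand(resname, chain_id, seq, [a for a in atoms if a.is_heavy])
                )
            else:
                out.add_residue(Residue(chain_id, resname, seq, icode, atoms))
    if n_atoms == 0:
        raise StructureFormatError(f"{path}: empty model")
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_line(record: str, serial: int, a: AnnotatedAtom,
                      bfactor: float = 0.0, chain_id: str | None = None) -> str:
    name = a.name
    if len(a.element) == 1 and len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    chain = (chain_id if chain_id is not None else a.chain_id)[:1] or "A"
    x, y, z = a.coords
    return (
        f"{record:<6s}{serial:>5d} {name_field} "
        f"{a.residue_name:>3s} {chain}{a.residue_seq:>4d}{a.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactor:6.2f}          "
        f"{a.element:>2s}\n"
    )


def write_structure(
    s: Structure,
    path: str | Path,
    extra_sasa_chain: dict[str, float] | None = None,
) -> Path:
    """Write *s* as a PDB file.

    When *extra_sasa_chain* maps atom ids to areas (Å²), the corresponding
    atoms are re-emitted under a separate chain 'X' with the per-atom SASA in
    the B-factor column.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 1
    for chain_id, residues in s.chains.items():
        for res in residues:
            for a in res.atoms:
                record = "HETATM" if a.is_hetero else "ATOM"
                lines.append(_format_atom_line(record, serial, a))
                serial += 1
        lines.append(f"TER   {serial:>5d}\n")
        serial += 1
    for lig in s.ligands:
        for a in lig.atoms:
            lines.append(_format_atom_line("HETATM", serial, a))
            serial += 1
    if extra_sasa_chain:
        amap = s.atom_map()
        for atom_id, area in extra_sasa_chain.items():
            a = amap.get(atom_id)
            if a is None:
                continue
            lines.append(_format_atom_line("ATOM", serial, a, bfactor=float(area), chain_id="X"))
            serial += 1
    lines.append("END\n")
    try:
        path.write_text("".join(lines))
    except OSError as exc:
        raise StructureFormatError(f"cannot write {path}: {exc}") from exc
    return path


def substructure_to_structure(sub: Substructure) -> Structure:
    """Wrap a substructure's atoms into a minimal Structure for writing."""
    out = Structure(f"{sub.structure_id}_{sub.role}")
    current: Residue | None = None
    for a in sub.atoms:
        if current is None or current.key != a.residue_key:
            current = Residue(a.chain_id, a.residue_name, a.residue_seq, a.insertion_code)
            out.add_residue(current)
        current.atoms.append(a)
    return out
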
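"""Rigid superposition and ligand pose transfer, plus FE-score computation.

A 3D alignment yields a Kabsch transform from the query frame into the
target frame; applying it to the probe ligand gives an initial pose. The
pose is then locally refined, either by an external docking engine
(AutoDock Vina ≥ 1.2, ``--local_only``) or by a bundled stub optimizer — a
clash-penalized rigid local search that lets the pipeline run end-to-end
without the engine. Stub energies are NOT publication-grade binding free
energies; they only preserve the FE-score algebra and its monotonicities.

FE-score = FE / (Shift + 0.1); a docking with FE-score < −1.5 is classified
as a true positive.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import Alignment3D
from .errors import DockingError, SuperpositionError
from .structure import Ligand, Structure

#: FE-score below which a docking counts as a true positive (strict <)
TP_FE_SCORE_THRESHOLD = -1.5
#: regularization constant in the FE-score denominator
FE_SCORE_EPSILON = 0.1


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping frame B onto frame A."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.rmsd)


@dataclass
class DockingResult:
    initial_pose: np.ndarray
    optimized_pose: np.ndarray
    fe: float
    shift: float
    fe_score: float
    is_tp: bool
    engine: str = "stub"
    metadata: dict = field(default_factory=dict)


def kabsch_superpose(points_a: np.ndarray, points_b: np.ndarray) -> RigidTransform:
    """Least-squares optimal proper rotation + translation mapping B onto A.

    Requires ≥ 3 point pairs that are not all collinear; reflections are
    never returned.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError(f"shape mismatch: {A.shape} vs {B.shape}")
    n = len(A)
    if n < 3:
        raise SuperpositionError(f"need ≥ 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinear (rank < 2) point sets leave the rotation underdetermined
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(A0, B0)
    R = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(n)
    t = ca - R @ cb
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def transfer_ligand(
    query: Structure,
    ligand: Ligand,
    alignment: Alignment3D,
    target: Structure,
) -> np.ndarray:
    """Probe-ligand heavy-atom coordinates carried into the target frame.

    The Kabsch transform is computed on the alignment's matched atoms
    (query side → target side) and applied to the ligand.
    """
    qmap = query.atom_map()
    tmap = target.atom_map()
    try:
        pts_q = np.array([qmap[a].coords for a, _ in alignment.pairs])
        pts_t = np.array([tmap[b].coords for _, b in alignment.pairs])
    except KeyError as exc:
        raise SuperpositionError(f"alignment references unknown atom {exc}") from exc
    transform = kabsch_superpose(pts_t, pts_q)  # maps query frame onto target
    lig_coords = np.array([a.coords for a in ligand.atoms if a.is_heavy])
    return transform.apply(lig_coords)


def pose_shift(p1: np.ndarray, p2: np.ndarray, mode: str = "rmsd") -> float:
    """Displacement (Å) between two poses of the same ligand."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise DockingError(f"pose shape mismatch: {p1.shape} vs {p2.shape}")
    if mode == "rmsd":
        return float(np.sqrt(((p1 - p2) ** 2).sum(axis=1).mean()))
    if mode == "centroid":
        return float(np.linalg.norm(p1.mean(axis=0) - p2.mean(axis=0)))
    raise DockingError(f"unknown shift mode {mode!r}")


def fe_score(fe: float, shift: float) -> float:
    """FE divided by (Shift + 0.1): large post-optimization shifts suppress
    significance even when the free energy is favorable."""
    if shift < 0:
        raise DockingError(f"negative shift {shift}")
    return fe / (shift + FE_SCORE_EPSILON)


def classify_tp(score: float, threshold: float = TP_FE_SCORE_THRESHOLD) -> bool:
    """True positive iff the FE-score is strictly below the threshold."""
    return score < threshold


# ---------------------------------------------------------------------------
# stub local optimizer
# ---------------------------------------------------------------------------

_CLASH_WEIGHT = 4.0
_WELL_DEPTH = 0.35
_WELL_OFFSET = 0.4
_WELL_WIDTH = 0.8
_CUTOFF = 8.0
#: harmonic tether to the initial pose (per Å², averaged over atoms): keeps
#: the refinement local, mirroring an engine's local-only mode; the reported
#: FE is the untethered energy at the optimized pose
_RESTRAINT = 1.0


def _stub_energy(lig: np.ndarray, lig_radii: np.ndarray,
                 rec_tree: cKDTree, rec_radii: np.ndarray) -> float:
    e = 0.0
    for coord, rl in zip(lig, lig_radii):
        idx = rec_tree.query_ball_point(coord, r=_CUTOFF)
        if not idx:
            continue
        d = np.linalg.norm(rec_tree.data[idx] - coord, axis=1)
        s = rec_radii[idx] + rl
        clash = np.clip(s - d, 0.0, None)
        e += _CLASH_WEIGHT * (clash ** 2).sum()
        e -= _WELL_DEPTH * np.exp(-((d - s - _WELL_OFFSET) ** 2) / _WELL_WIDTH).sum()
    return e


def _pose_from_params(params: np.ndarray, pose0: np.ndarray, center: np.ndarray) -> np.ndarray:
    shift_vec = params[:3]
    rot = Rotation.from_rotvec(params[3:])
    return (pose0 - center) @ rot.as_matrix().T + center + shift_vec


def optimize_pose(
    target: Structure,
    pose: np.ndarray,
    ligand_radii: np.ndarray | None = None,
    engine: str = "stub",
    engine_config: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Locally refine a rigid ligand pose against the target; returns
    (FE, optimized pose).

    ``engine='vina'`` shells out to an AutoDock Vina executable in
    local-only mode (receptor kept rigid); ``engine='stub'`` runs the
    bundled clash-penalized Nelder–Mead search and is deterministic.
    """
    pose = np.asarray(pose, dtype=float)
    if engine == "vina":
        return _vina_optimize(target, pose, engine_config or {})
    if engine != "stub":
        raise DockingError(f"unknown engine {engine!r}")
    rec_atoms = [a for a in target.atoms() if a.is_heavy]
    if not rec_atoms:
        raise DockingError("target has no heavy atoms")
    rec_coords = np.array([a.coords for a in rec_atoms])
    rec_radii = np.array([a.vdw_radius for a in rec_atoms])
    tree = cKDTree(rec_coords)
    if ligand_radii is None:
        ligand_radii = np.full(len(pose), 1.70)
    center = pose.mean(axis=0)

    def objective(params: np.ndarray) -> float:
        moved = _pose_from_params(params, pose, center)
        tether = _RESTRAINT * float(((moved - pose) ** 2).sum(axis=1).mean())
        return _stub_energy(moved, ligand_radii, tree, rec_radii) + tether

    x0 = np.zeros(6)
    simplex = np.vstack([x0, np.eye(6) * np.array([0.5] * 3 + [0.2] * 3)])
    res = minimize(
        objective,
        x0=x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 2000,
                 "initial_simplex": simplex},
    )
    optimized = _pose_from_params(res.x, pose, center)
    fe = _stub_energy(optimized, ligand_radii, tree, rec_radii)
    return float(fe), optimized


def dock_transferred_pose(
    query: Structure,
    ligand: Ligand,
    alignment: Alignment3D,
    target: Structure,
    engine: str = "stub",
    shift_mode: str = "rmsd",
    engine_config: dict | None = None,
) -> DockingResult:
    """Transfer → optimize → FE-score, in one call."""
    initial = transfer_ligand(query, ligand, alignment, target)
    radii = np.array([a.vdw_radius for a in ligand.atoms if a.is_heavy])
    fe, optimized = optimize_pose(
        target, initial, ligand_radii=radii, engine=engine, engine_config=engine_config
    )
    shift = pose_shift(initial, optimized, mode=shift_mode)
    score = fe_score(fe, shift)
    return DockingResult(
        initial_pose=initial,
        optimized_pose=optimized,
        fe=fe,
        shift=shift,
        fe_score=score,
        is_tp=classify_tp(score),
        engine=engine,
        metadata={"shift_mode": shift_mode, "n_alignment_pairs": alignment.n},
    )


# ---------------------------------------------------------------------------
# external engine (AutoDock Vina) wrapper
# ---------------------------------------------------------------------------

_PDBQT_TYPES = {"C": "C", "N": "N", "O": "OA", "S": "SA", "P": "P",
                "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "SE": "Se"}


def write_pdbqt(atoms_coords: np.ndarray, elements: list[str], path: Path,
                rigid: bool = True) -> None:
    """Minimal PDBQT writer: no torsion tree (local-only rigid docking)."""
    lines = []
    if not rigid:
        lines.append("ROOT\n")
    for i, (coord, el) in enumerate(zip(atoms_coords, elements), start=1):
        t = _PDBQT_TYPES.get(el.upper(), el.upper()[:2])
        x, y, z = coord
        lines.append(
            f"ATOM  {i:>5d}  {el.upper():<3s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}    {0.0:6.3f} {t}\n"
        )
    if not rigid:
        lines.append("ENDROOT\nTORSDOF 0\n")
    path.write_text("".join(lines))


def _vina_optimize(target: Structure, pose: np.ndarray,
                   engine_config: dict) -> tuple[float, np.ndarray]:
    exe = engine_config.get("executable", "vina")
    if shutil.which(exe) is None:
        raise DockingError(f"docking engine {exe!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        rec_atoms = [a for a in target.atoms() if a.is_heavy]
        write_pdbqt(np.array([a.coords for a in rec_atoms]),
                    [a.element for a in rec_atoms], tmp / "receptor.pdbqt")
        write_pdbqt(pose, engine_config.get("ligand_elements", ["C"] * len(pose)),
                    tmp / "ligand.pdbqt", rigid=False)
        out = tmp / "out.pdbqt"
        cmd = [exe, "--receptor", str(tmp / "receptor.pdbqt"),
               "--ligand", str(tmp / "ligand.pdbqt"),
               "--local_only", "--out", str(out)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise DockingError(f"engine failed: {proc.stderr.strip()}")
        fe = None
        for line in proc.stdout.splitlines():
            if "Affinity" in line:
                fe = float(line.split()[1])
        coords = []
        for line in out.read_text().splitlines():
            if line.startswith(("ATOM", "HETATM")):
                coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        if fe is None or not coords:
            raise DockingError("engine produced no affinity/pose")
        return fe, np.array(coords)
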
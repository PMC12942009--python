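"""Batch orchestration: end-to-end screens over substructure databases.

Every output table starts with comment lines embedding the fully resolved
configuration, so a result file is always auditable back to its thresholds.
Per-target failures are logged and counted, never fatal to the batch.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from joblib import Parallel, delayed

from .annotation import SubstitutionModel, annotate_structure
from .config import SlamConfig
from .core import Alignment3D, slam_align
from .errors import SlamError
from .extraction import extract_ligand_cavity
from .structure import Structure, Substructure, heavy_atoms, read_structure

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["query_id", "target_id", "N", "r", "ncorr5", "pairs"]


def _pairs_to_str(al: Alignment3D) -> str:
    return ";".join(f"{a}:{b}" for a, b in al.pairs)


def structure_as_substructure(s: Structure, role: str = "surface_patch") -> Substructure:
    """Treat a whole (fragment) structure as one substructure."""
    return Substructure(
        structure_id=s.structure_id,
        chain_id="*",
        role=role,
        atoms=heavy_atoms(s),
        anchor=s.structure_id,
    )


def query_substructure(path: str | Path, config: SlamConfig) -> Substructure:
    """Load a query: a probe complex (cavity around its first ligand) or,
    when the file carries no ligand, the whole fragment."""
    s = read_structure(path)
    annotate_structure(s, tolerance=config.contact_tolerance)
    if s.ligands:
        cavity = extract_ligand_cavity(
            s, s.ligands[0],
            radius=config.cavity_radius,
            min_atoms=config.cavity_min_atoms,
        )
        if cavity is None:
            raise SlamError(
                f"{path}: cavity below {config.cavity_min_atoms} atoms"
            )
        return cavity
    return structure_as_substructure(s, role="ligand_cavity")


def _align_one(query_sub: Substructure, target_path: Path,
               config: SlamConfig, model: SubstitutionModel):
    try:
        t = read_structure(target_path)
        annotate_structure(t, tolerance=config.contact_tolerance)
        target_sub = structure_as_substructure(t)
        alignments = slam_align(query_sub, target_sub, config, model)
    except (SlamError, OSError) as exc:
        return {"error": f"{target_path}: {exc}"}
    if not alignments:
        return {
            "query_id": query_sub.structure_id,
            "target_id": t.structure_id,
            "N": 0, "r": float("nan"), "ncorr5": 0.0, "pairs": "",
        }
    top = alignments[0]
    return {
        "query_id": query_sub.structure_id,
        "target_id": t.structure_id,
        "N": top.n,
        "r": top.r,
        "ncorr5": top.ncorr5,
        "pairs": _pairs_to_str(top),
    }


def run_screen(
    config: SlamConfig,
    query_path: str | Path,
    targets_manifest: str | Path,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, int]:
    """Screen one query cavity against every target of a manifest.

    The manifest is a TSV with a ``path`` column (relative to its own
    directory). Returns the results table (manifest order) and the number
    of row-level errors.
    """
    manifest_path = Path(targets_manifest)
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = manifest_path.parent
    query_sub = query_substructure(query_path, config)
    model = SubstitutionModel(
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        chem_weight=config.chem_weight,
    )
    rows = Parallel(n_jobs=config.n_jobs)(
        delayed(_align_one)(query_sub, base / rel, config, model)
        for rel in manifest["path"]
    )
    errors = 0
    records = []
    for row in rows:
        if "error" in row:
            errors += 1
            logger.error("%s", row["error"])
        else:
            records.append(row)
    df = pd.DataFrame(records, columns=RESULT_COLUMNS)
    if out_path is not None:
        write_table_with_config(df, out_path, config, extra={"n_errors": errors})
    return df, errors


def write_table_with_config(
    df: pd.DataFrame, path: str | Path, config: SlamConfig, extra: dict | None = None
) -> None:
    """TSV with the resolved config embedded as leading comment lines."""
    path = Path(path)
    header = "# config: " + json.dumps(config.to_dict(), sort_keys=True) + "\n"
    if extra:
        header += "# run: " + json.dumps(extra, sort_keys=True) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
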
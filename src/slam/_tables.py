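"""Bundled element and residue tables (van der Waals radii, Pauling
electronegativities, hydrogen-bond donor/acceptor templates).

All tables live as YAML files under ``slam/data`` so they can be audited and
overridden; the loaders here cache them per process.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import AnnotationError

#: residues treated as part of the polymer chain even though they appear as
#: HETATM records (configurable at read time)
MODIFIED_RESIDUE_WHITELIST = frozenset({"MSE", "SEP", "TPO", "PTR", "CSO"})

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})


def _load_yaml(name: str) -> dict:
    with resources.files("slam.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    return {str(k).upper(): float(v) for k, v in _load_yaml("vdw_radii.yaml").items()}


@lru_cache(maxsize=None)
def electronegativities() -> dict[str, float]:
    return {str(k).upper(): float(v) for k, v in _load_yaml("electronegativity.yaml").items()}


@lru_cache(maxsize=None)
def hbond_templates() -> dict:
    raw = _load_yaml("hbond_templates.yaml")
    return {
        "backbone": {k: tuple(v) for k, v in raw["backbone"].items()},
        "residues": {
            res: {atom: tuple(flags) for atom, flags in atoms.items()}
            for res, atoms in raw["residues"].items()
        },
        "element_fallback": {k: tuple(v) for k, v in raw["element_fallback"].items()},
    }


def vdw_radius(element: str) -> float:
    """Van der Waals radius of *element* in Å; unknown elements raise."""
    try:
        return vdw_radii()[element.upper()]
    except KeyError:
        raise AnnotationError(f"no van der Waals radius for element {element!r}") from None


def electronegativity(element: str) -> float:
    try:
        return electronegativities()[element.upper()]
    except KeyError:
        raise AnnotationError(f"no Pauling electronegativity for element {element!r}") from None
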
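"""Molecular species: XYZ I/O and the geometric descriptors the cage model needs.

A :class:`MolecularStructure` is an element list plus Cartesian coordinates in
Angstrom.  Two descriptors feed the hard-sphere cage approximation:

* ``centroid`` — the unweighted mean atom position c_s (atomic masses are
  deliberately ignored);
* ``molecular_radius`` — the root-mean-square distance of the atoms from that
  centroid.  This is the radius-of-gyration formula with every atom given unit
  weight, so it measures the spatial extent of the atom positions rather than
  the mass distribution.

The module also builds the packaged toy geometries used throughout the test
suite and the demo configurations (iodoform photochemistry, cyclohexane,
cis/trans azobenzene and its 4,4'-dibromo analogue).  These are synthetic
fixture geometries assembled from standard bond lengths or an RDKit ETKDG
embedding — convenient, reproducible stand-ins, not refined experimental
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chem_data

__all__ = [
    "MolecularStructure",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "centroid",
    "molecular_radius",
    "total_electrons",
    "build_fixture",
    "FIXTURE_SPECIES",
]


@dataclass(frozen=True)
class MolecularStructure:
    """One chemical species: element symbols plus k x 3 coordinates (Angstrom)."""

    name: str
    elements: tuple[str, ...]
    coordinates: np.ndarray
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        coords = coords.reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) < 1:
            raise ValueError("a structure needs at least one atom")
        if coords.shape[0] != len(self.elements):
            raise ValueError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for el in self.elements:
            chem_data.atomic_number(el)  # raises UnsupportedElementError

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def element_counts(self) -> dict[str, int]:
        """Number of atoms per element type (the N_i of the cage sum)."""
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        return counts

    def translated(self, shift) -> "MolecularStructure":
        return MolecularStructure(
            self.name, self.elements, self.coordinates + np.asarray(shift, float),
            self.comment,
        )

    def rotated(self, rotation_matrix) -> "MolecularStructure":
        rot = np.asarray(rotation_matrix, dtype=float)
        return MolecularStructure(
            self.name, self.elements, self.coordinates @ rot.T, self.comment
        )


class XYZParseError(ValueError):
    """Malformed XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_xyz(path) -> MolecularStructure:
    """Read a standard XYZ file (count line, comment line, element x y z rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError("empty file", 1)
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"atom count expected, got {lines[0]!r}", 1) from None
    if count < 1:
        raise XYZParseError(f"atom count must be >= 1, got {count}", 1)
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < count:
        raise XYZParseError(
            f"declared {count} atoms but found {len(body)} atom rows", 2 + len(body)
        )
    elements: list[str] = []
    coords = np.empty((count, 3))
    for i, line in enumerate(body[:count]):
        tok = line.split()
        lineno = 3 + i
        if len(tok) < 4:
            raise XYZParseError(f"expected 'element x y z', got {line!r}", lineno)
        el = tok[0]
        try:
            chem_data.atomic_number(el)
        except chem_data.UnsupportedElementError:
            raise XYZParseError(f"unknown element {el!r}", lineno) from None
        try:
            coords[i] = [float(v) for v in tok[1:4]]
        except ValueError:
            raise XYZParseError(f"non-numeric coordinate in {line!r}", lineno) from None
        elements.append(el)
    return MolecularStructure(path.stem, tuple(elements), coords, comment)


def write_xyz(structure: MolecularStructure, path) -> None:
    """Write a structure as standard XYZ (coordinates at 6 decimals, Angstrom)."""
    path = Path(path)
    lines = [str(structure.n_atoms), structure.comment or structure.name]
    for el, (x, y, z) in zip(structure.elements, structure.coordinates):
        lines.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(lines) + "\n")


def centroid(structure: MolecularStructure) -> np.ndarray:
    """Unweighted mean atom position c_s (Angstrom)."""
    return structure.coordinates.mean(axis=0)


def molecular_radius(structure: MolecularStructure) -> float:
    """RMS distance of the atoms from the unweighted centroid (Angstrom).

    Zero for a single atom; invariant under rigid rotation and translation.
    """
    d = structure.coordinates - centroid(structure)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def total_electrons(structure: MolecularStructure) -> int:
    """Sum of atomic numbers; the q -> 0 Debye intensity is its square."""
    return sum(chem_data.atomic_number(el) for el in structure.elements)


# ---------------------------------------------------------------------------
# Packaged toy geometries
# ---------------------------------------------------------------------------

_DEG = np.pi / 180.0


def _iodoform() -> MolecularStructure:
    # CHI3: quasi-tetrahedral, C-H 1.09 A, C-I 2.15 A, H-C-I 107.6 deg
    theta = 107.6 * _DEG
    ch, ci = 1.09, 2.15
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, ch]]
    elements = ["C", "H"]
    for phi in (0.0, 120.0 * _DEG, 240.0 * _DEG):
        coords.append(
            [
                ci * np.sin(theta) * np.cos(phi),
                ci * np.sin(theta) * np.sin(phi),
                ci * np.cos(theta),
            ]
        )
        elements.append("I")
    return MolecularStructure("chi3", tuple(elements), np.array(coords),
                              "synthetic toy geometry: iodoform CHI3")


def _chi2i_isomer() -> MolecularStructure:
    # iso-CHI2-I: one iodine displaced to an I-I contact (2.90 A) after
    # photoinduced isomerisation; toy geometry from standard bond lengths.
    base = _iodoform()
    coords = base.coordinates.copy()
    # move I3 from carbon onto I2 along an I-I direction
    i2 = coords[3]
    direction = np.array([np.cos(20 * _DEG), 0.0, -np.sin(20 * _DEG)])
    coords[4] = i2 + 2.90 * direction
    return MolecularStructure("chi2i", base.elements, coords,
                              "synthetic toy geometry: iso-CHI2-I isomer")


def _chi2_radical() -> MolecularStructure:
    # CHI2 radical: planar, C-I 2.12 A, I-C-I 114 deg
    half = 57.0 * _DEG
    ci, ch = 2.12, 1.08
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.0, ch],
            [ci * np.sin(half), 0.0, -ci * np.cos(half)],
            [-ci * np.sin(half), 0.0, -ci * np.cos(half)],
        ]
    )
    return MolecularStructure("chi2", ("C", "H", "I", "I"), coords,
                              "synthetic toy geometry: CHI2 radical")


def _iodine_atom() -> MolecularStructure:
    return MolecularStructure("i_atom", ("I",), np.zeros((1, 3)),
                              "iodine atom (radical channel fragment)")


_RDKIT_SEED = 20210  # fixed so fixture geometries are reproducible


def _embed_smiles(smiles: str, name: str, comment: str) -> MolecularStructure:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = _RDKIT_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {name}")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return MolecularStructure(name, elements, coords, comment)


def _cyclohexane() -> MolecularStructure:
    return _embed_smiles("C1CCCCC1", "cyclohexane",
                         "synthetic toy geometry: cyclohexane chair (ETKDG)")


def _azobenzene(isomer: str) -> MolecularStructure:
    smiles = {"trans": r"c1ccc(/N=N/c2ccccc2)cc1",
              "cis": r"c1ccc(/N=N\c2ccccc2)cc1"}[isomer]
    return _embed_smiles(
        smiles, f"ab_{isomer}",
        f"synthetic toy geometry: {isomer}-azobenzene (ETKDG)",
    )


def _para_hydrogen_indices(structure: MolecularStructure) -> list[int]:
    """Indices of the two H atoms para to the azo-attached ring carbons.

    Works geometrically: for each phenyl ring the para carbon is the ring
    carbon farthest from the attached nitrogen; its bonded hydrogen is the
    substitution site.
    """
    elements = structure.elements
    coords = structure.coordinates
    n_idx = [i for i, el in enumerate(elements) if el == "N"]
    c_idx = [i for i, el in enumerate(elements) if el == "C"]
    h_idx = [i for i, el in enumerate(elements) if el == "H"]
    out = []
    for n in n_idx:
        # ipso carbon: nearest C to this N
        ipso = min(c_idx, key=lambda c: np.linalg.norm(coords[c] - coords[n]))
        # ring carbons: 6 nearest carbons to the ipso (including itself)
        ring = sorted(c_idx, key=lambda c: np.linalg.norm(coords[c] - coords[ipso]))[:6]
        para = max(ring, key=lambda c: np.linalg.norm(coords[c] - coords[ipso]))
        h = min(h_idx, key=lambda h_: np.linalg.norm(coords[h_] - coords[para]))
        out.append((para, h))
    return [h for _, h in out]


def _dibromo_azobenzene(isomer: str) -> MolecularStructure:
    """4,4'-dibromoazobenzene built from azobenzene by substituting the two
    para hydrogens with bromine (C-Br stretched to 1.89 A along the old C-H
    direction); all other atoms are untouched, isolating the heavy-atom effect.
    """
    ab = _azobenzene(isomer)
    elements = list(ab.elements)
    coords = ab.coordinates.copy()
    c_idx = [i for i, el in enumerate(elements) if el == "C"]
    for h in _para_hydrogen_indices(ab):
        c = min(c_idx, key=lambda ci: np.linalg.norm(coords[ci] - coords[h]))
        direction = coords[h] - coords[c]
        coords[h] = coords[c] + 1.89 * direction / np.linalg.norm(direction)
        elements[h] = "Br"
    return MolecularStructure(
        f"br2ab_{isomer}", tuple(elements), coords,
        f"synthetic toy geometry: 4,4'-dibromo {isomer}-azobenzene (para H->Br)",
    )


_BUILDERS = {
    "chi3": _iodoform,
    "chi2i": _chi2i_isomer,
    "chi2": _chi2_radical,
    "i_atom": _iodine_atom,
    "cyclohexane": _cyclohexane,
    "ab_trans": lambda: _azobenzene("trans"),
    "ab_cis": lambda: _azobenzene("cis"),
    "br2ab_trans": lambda: _dibromo_azobenzene("trans"),
    "br2ab_cis": lambda: _dibromo_azobenzene("cis"),
}

FIXTURE_SPECIES: tuple[str, ...] = tuple(_BUILDERS)

_FIXTURE_CACHE: dict[str, MolecularStructure] = {}


def build_fixture(name: str) -> MolecularStructure:
    """Return one of the packaged toy geometries by name (see FIXTURE_SPECIES)."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_SPECIES}")
    if name not in _FIXTURE_CACHE:
        _FIXTURE_CACHE[name] = _BUILDERS[name]()
    return _FIXTURE_CACHE[name]
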
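"""Solute-solvent cross (cage) term via the hard-sphere pair-distribution model.

The cage contribution of one solute molecule is the sine Fourier transform of
solute-solvent pair-distribution functions,

    S_cage(q) = sum_i sum_j f_i(q) f_j(q) N_i n_j
                * integral 4 pi r^2 [g_ij(r) - 1] sin(qr)/(qr) dr,

where i runs over solute atom types (N_i atoms in the solute), j over solvent
atom types, and n_j is the bulk number density of solvent atoms of type j
(1/A^3).  Expressing the double-counting normalisation through the bulk
number density removes any simulation-box dependence and yields e.u. per
solute molecule.

Instead of molecular-dynamics RDFs the g_ij are approximated by trapezoids:
zero inside the van der Waals contact V_ij, unity beyond V_ij + R_s (R_s the
solute's unweighted RMS radius), linear in between.  Because g - 1 vanishes
beyond V_ij + R_s the transform integral has compact support and needs no
windowing.  Externally computed RDFs can be loaded from two-column text and
used interchangeably; their g - 1 tail beyond the last tabulated r is taken
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from . import chem_data
from .debye import PER_SOLUTE, PER_SOLVENT, ReactionChannel, ScatteringCurve
from .structures import MolecularStructure, molecular_radius

__all__ = [
    "PairDistribution",
    "SolventComposition",
    "hard_sphere_gr",
    "hard_sphere_pdfs",
    "cage_intensity",
    "cage_difference",
    "load_rdf",
]

AVOGADRO = 6.02214076e23
_R_STEP = 0.0025  # A; with knot-aligned segments this converges well below 1e-6
_R_GUARD = 1.0    # A beyond the outer knot


@dataclass(frozen=True)
class PairDistribution:
    """g_ij(r) between one solute element i and one solvent element j."""

    r: np.ndarray
    g: np.ndarray
    element_i: str
    element_j: str

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        if r.ndim != 1 or np.any(np.diff(r) <= 0) or r[0] < 0:
            raise ValueError("r must be non-negative and strictly increasing")
        if g.shape != r.shape or np.any(g < 0) or not np.all(np.isfinite(g)):
            raise ValueError("g must align with r, be finite and non-negative")


@dataclass(frozen=True)
class SolventComposition:
    """Atoms per solvent molecule and the solvent's bulk number density.

    ``number_density`` is in molecules per cubic Angstrom; the per-element
    atomic number density entering the cage sum is
    ``number_density * atoms_per_molecule[j]``.
    """

    atoms_per_molecule: Mapping[str, int]
    number_density: float

    def __post_init__(self) -> None:
        comp = dict(self.atoms_per_molecule)
        object.__setattr__(self, "atoms_per_molecule", comp)
        if not comp:
            raise ValueError("solvent composition is empty")
        for el, n in comp.items():
            chem_data.atomic_number(el)
            if int(n) != n or n <= 0:
                raise ValueError(f"atom count for {el} must be a positive integer")
        if self.number_density <= 0:
            raise ValueError("number density must be positive")

    @classmethod
    def from_mass_density(
        cls, atoms_per_molecule: Mapping[str, int],
        mass_density_g_ml: float, molar_mass_g_mol: float,
    ) -> "SolventComposition":
        """Build from mass density (g/mL) and molar mass (g/mol)."""
        n = mass_density_g_ml / molar_mass_g_mol * AVOGADRO * 1e-24  # molecules/A^3
        return cls(atoms_per_molecule, n)

    def atom_number_density(self, element: str) -> float:
        return self.number_density * self.atoms_per_molecule[element]


def hard_sphere_gr(
    v_ij: float, r_s: float, r: np.ndarray,
    element_i: str = "X", element_j: str = "X",
) -> PairDistribution:
    """Trapezoidal hard-sphere g(r): 0 below V_ij, 1 above V_ij + R_s.

    With R_s = 0 the trapezoid degenerates to a step at V_ij.
    """
    if v_ij <= 0:
        raise ValueError("contact distance V_ij must be positive")
    if r_s < 0:
        raise ValueError("solute radius R_s must be non-negative")
    r = np.asarray(r, dtype=float)
    if r_s == 0.0:
        g = np.where(r < v_ij, 0.0, 1.0)
    else:
        g = np.clip((r - v_ij) / r_s, 0.0, 1.0)
    return PairDistribution(r, g, element_i, element_j)


def _pair_grid(v_ij: float, r_s: float) -> np.ndarray:
    """Integration grid with the trapezoid knots exactly on-grid.

    The integrand has slope discontinuities at V_ij and V_ij + R_s; placing
    both knots on the grid keeps the trapezoidal rule at its O(h^2) accuracy.
    """
    segments = []
    bounds = [0.0, v_ij, v_ij + r_s, v_ij + r_s + _R_GUARD]
    for lo, hi in zip(bounds, bounds[1:]):
        if hi - lo <= 0:
            continue
        n = max(2, int(np.ceil((hi - lo) / _R_STEP)) + 1)
        segments.append(np.linspace(lo, hi, n))
    grid = np.concatenate(segments)
    return np.unique(grid)


def hard_sphere_pdfs(
    solute: MolecularStructure, solvent: SolventComposition,
    r_s: Optional[float] = None,
) -> dict[tuple[str, str], PairDistribution]:
    """One trapezoidal PDF per (solute element, solvent element) pair.

    R_s defaults to the solute's unweighted RMS radius.
    """
    if r_s is None:
        r_s = molecular_radius(solute)
    pdfs: dict[tuple[str, str], PairDistribution] = {}
    for el_i in sorted(solute.element_counts()):
        for el_j in sorted(solvent.atoms_per_molecule):
            v_ij = chem_data.combined_vdw(el_i, el_j)
            r = _pair_grid(v_ij, r_s)
            pdfs[(el_i, el_j)] = hard_sphere_gr(v_ij, r_s, r, el_i, el_j)
    return pdfs


def _pair_transform(pdf: PairDistribution, q: np.ndarray) -> np.ndarray:
    """integral 4 pi r^2 (g-1) sinc(qr) dr by the trapezoidal rule (A^3)."""
    r, g = pdf.r, pdf.g
    h = g - 1.0
    qr = q[:, None] * r[None, :]
    kernel = 4.0 * np.pi * r[None, :] ** 2 * h[None, :] * np.sinc(qr / np.pi)
    return np.trapezoid(kernel, r, axis=1)


def cage_intensity(
    solute: MolecularStructure,
    solvent: SolventComposition,
    pdfs: Optional[Mapping[tuple[str, str], PairDistribution]] = None,
    q: Optional[np.ndarray] = None,
    r_s: Optional[float] = None,
) -> ScatteringCurve:
    """Cage term of one solute molecule, e.u. per solute molecule.

    If ``pdfs`` is omitted the trapezoidal hard-sphere set is built from the
    solute's own radius.  A supplied mapping must cover every
    (solute element, solvent element) pair.
    """
    if q is None:
        raise ValueError("a q grid is required")
    q = np.asarray(q, dtype=float)
    if pdfs is None:
        pdfs = hard_sphere_pdfs(solute, solvent, r_s=r_s)
    counts = solute.element_counts()
    intensity = np.zeros_like(q)
    for el_i, n_i in sorted(counts.items()):
        f_i = chem_data.form_factor(el_i, q)
        for el_j in sorted(solvent.atoms_per_molecule):
            pdf = pdfs.get((el_i, el_j))
            if pdf is None:
                raise KeyError(
                    f"missing pair distribution for solute {el_i} / solvent {el_j}"
                )
            f_j = chem_data.form_factor(el_j, q)
            n_j = solvent.atom_number_density(el_j)
            intensity += f_i * f_j * n_i * n_j * _pair_transform(pdf, q)
    return ScatteringCurve(q, intensity, normalization=PER_SOLUTE)


def species_cage_intensity(fragments, solvent: SolventComposition, q) -> ScatteringCurve:
    """Cage term of a multi-fragment species: each fragment carries its own
    radius and element inventory; fragment terms add."""
    if isinstance(fragments, MolecularStructure):
        fragments = (fragments,)
    q = np.asarray(q, dtype=float)
    total = np.zeros_like(q)
    for frag in fragments:
        total += cage_intensity(frag, solvent, q=q).intensity
    return ScatteringCurve(q, total, normalization=PER_SOLUTE)


def cage_difference(
    channel: ReactionChannel,
    solvent: SolventComposition,
    c_solu: float,
    c_solv: float,
    q: np.ndarray,
) -> ScatteringCurve:
    """Cage difference signal of a reaction channel, e.u. per solvent molecule."""
    if c_solu <= 0 or c_solv <= 0:
        raise ValueError("concentrations must be positive")
    q = np.asarray(q, dtype=float)
    s_r = species_cage_intensity(channel.reactant, solvent, q).intensity
    weighted = np.zeros_like(q)
    for fragments, fraction in channel.products:
        weighted += fraction * species_cage_intensity(fragments, solvent, q).intensity
    scale = (c_solu / c_solv) * channel.excitation_fraction
    return ScatteringCurve(q, scale * (weighted - s_r), normalization=PER_SOLVENT)


def load_rdf(path, element_i: str, element_j: str) -> PairDistribution:
    """Load an externally computed RDF from two-column text (r in A, g)."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) < 2:
            raise ValueError(f"{path.name} line {lineno}: expected 'r g'")
        try:
            rows.append((float(tok[0]), float(tok[1])))
        except ValueError:
            raise ValueError(
                f"{path.name} line {lineno}: non-numeric value in {line!r}"
            ) from None
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    r = np.array([x for x, _ in rows])
    g = np.array([y for _, y in rows])
    if np.any(np.diff(r) <= 0):
        raise ValueError(f"{path.name}: r column must be strictly increasing")
    if np.any(g < 0):
        raise ValueError(f"{path.name}: g values must be non-negative")
    return PairDistribution(r, g, element_i, element_j)
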
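"""Debye-equation scattering and the solute-only difference term.

For randomly oriented molecules the elastic X-ray scattering of one species is

    S(q) = sum_m sum_n f_m(q) f_n(q) sin(q r_nm) / (q r_nm),

with the m = n diagonal contributing f(q)^2 (sinc -> 1).  The solute-only
difference signal of a photoreaction, scaled to one mole of solvent, is

    dS_solute(q) = (c_solu / c_solv) * r_exc * [ sum_p x_p S_p(q) - S_r(q) ],

where r_exc is the excitation fraction (the fraction of solute molecules
converted), x_p the branching fraction into product channel p, and S_r / S_p
the reactant / product Debye intensities.  Multi-fragment product channels
(e.g. a radical pair after dissociation) contribute the sum of their
fragments' intensities without cross terms — fragments are assumed
uncorrelated once separated.

Intensities are in electron units (e.u.); curves carry a normalization tag
distinguishing per-solute-molecule species intensities from per-solvent-
molecule difference signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import chem_data
from .structures import MolecularStructure

__all__ = [
    "PER_SOLUTE",
    "PER_SOLVENT",
    "ScatteringCurve",
    "ReactionChannel",
    "default_q_grid",
    "debye_intensity",
    "species_intensity",
    "solute_difference",
]

PER_SOLUTE = "per_solute_molecule"
PER_SOLVENT = "per_solvent_molecule"


@dataclass(frozen=True)
class ScatteringCurve:
    """A curve on a q grid: intensity (e.u.) with optional per-point sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    normalization: str = PER_SOLUTE

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", intensity)
        if q.ndim != 1 or np.any(np.diff(q) <= 0) or np.any(q < 0):
            raise ValueError("q must be 1-D, non-negative and strictly increasing")
        if intensity.shape != q.shape:
            raise ValueError("intensity must align with q")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            sigma = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sigma)
            if sigma.shape != q.shape:
                raise ValueError("sigma must align with q")
            if np.any(sigma < 0):
                raise ValueError("sigma must be non-negative")

    def with_intensity(self, intensity, sigma=None) -> "ScatteringCurve":
        return ScatteringCurve(self.q, intensity, sigma, self.normalization)

    def same_grid(self, other: "ScatteringCurve") -> bool:
        return self.q.shape == other.q.shape and bool(np.allclose(self.q, other.q))


def require_same_grid(*curves: ScatteringCurve) -> np.ndarray:
    first = curves[0]
    for c in curves[1:]:
        if not first.same_grid(c):
            raise ValueError("scattering curves are on different q grids")
    return first.q


@dataclass(frozen=True)
class ReactionChannel:
    """Reactant plus product channels with branching fractions.

    ``products`` maps each channel to (fragment tuple, branching fraction);
    fractions must be non-negative and sum to 1.  ``excitation_fraction`` is
    the converted fraction r_exc of all solute molecules.
    """

    reactant: tuple[MolecularStructure, ...]
    products: tuple[tuple[tuple[MolecularStructure, ...], float], ...]
    excitation_fraction: float

    def __post_init__(self) -> None:
        reactant = _as_fragments(self.reactant)
        products = tuple(
            (_as_fragments(frags), float(frac)) for frags, frac in self.products
        )
        object.__setattr__(self, "reactant", reactant)
        object.__setattr__(self, "products", products)
        fracs = [frac for _, frac in products]
        if any(f < 0 for f in fracs):
            raise ValueError("branching fractions must be non-negative")
        if fracs and abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"branching fractions must sum to 1, got {sum(fracs)}")
        if not 0.0 <= self.excitation_fraction <= 1.0:
            raise ValueError("excitation fraction must lie in [0, 1]")


def _as_fragments(obj) -> tuple[MolecularStructure, ...]:
    if isinstance(obj, MolecularStructure):
        return (obj,)
    return tuple(obj)


def default_q_grid() -> np.ndarray:
    """0.3 to 8.0 1/A at 0.01 1/A spacing — covers the usual TRXL display range."""
    return np.linspace(0.3, 8.0, 771)


def _sinc(x: np.ndarray) -> np.ndarray:
    # np.sinc is sin(pi x)/(pi x); rescale. Handles x=0 exactly.
    return np.sinc(x / np.pi)


def debye_intensity(structure: MolecularStructure, q: np.ndarray) -> ScatteringCurve:
    """Debye intensity of one species, in e.u. per solute molecule.

    Includes the self (m = n) terms, so S(0) = (sum_n Z_n)^2 up to the
    form-factor fit accuracy.
    """
    q = np.asarray(q, dtype=float)
    elements = structure.elements
    unique = sorted(set(elements))
    f_by_el = {el: chem_data.form_factor(el, q) for el in unique}
    f = np.stack([f_by_el[el] for el in elements])  # (k, nq)
    if structure.n_atoms == 1:
        intensity = f[0] ** 2
    else:
        rij = squareform(pdist(structure.coordinates))  # (k, k)
        phase = _sinc(q[None, None, :] * rij[:, :, None])  # (k, k, nq)
        intensity = np.einsum("iq,jq,ijq->q", f, f, phase)
    return ScatteringCurve(q, intensity, normalization=PER_SOLUTE)


def species_intensity(
    fragments: Sequence[MolecularStructure], q: np.ndarray
) -> ScatteringCurve:
    """Intensity of a (possibly multi-fragment) species: fragment sum, no cross terms."""
    fragments = _as_fragments(fragments)
    q = np.asarray(q, dtype=float)
    total = np.zeros_like(q)
    for frag in fragments:
        total += debye_intensity(frag, q).intensity
    return ScatteringCurve(q, total, normalization=PER_SOLUTE)


def solute_difference(
    channel: ReactionChannel,
    c_solu: float,
    c_solv: float,
    q: np.ndarray,
) -> ScatteringCurve:
    """Solute-only difference signal, e.u. per solvent molecule.

    Linear in the excitation fraction and in c_solu / c_solv; identically
    zero when nothing is excited or the products equal the reactant.
    """
    if c_solu <= 0 or c_solv <= 0:
        raise ValueError("concentrations must be positive")
    q = np.asarray(q, dtype=float)
    s_r = species_intensity(channel.reactant, q).intensity
    weighted = np.zeros_like(q)
    for fragments, fraction in channel.products:
        weighted += fraction * species_intensity(fragments, q).intensity
    scale = (c_solu / c_solv) * channel.excitation_fraction
    return ScatteringCurve(q, scale * (weighted - s_r), normalization=PER_SOLVENT)
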
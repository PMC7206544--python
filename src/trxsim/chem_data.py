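"""Atomic constants for X-ray scattering: form factors and van der Waals radii.

Form factors use the analytic Cromer-Mann parameterization (four Gaussians
plus a constant, International Tables for Crystallography Vol. C convention)

    f(q) = sum_{i=1..4} a_i exp(-b_i s^2) + c,    s = q / (4 pi),

with ``q`` the momentum transfer magnitude in inverse Angstrom.  At q = 0 the
form factor equals the number of electrons Z of the neutral atom (to within
the fit accuracy of the tabulation, < 0.1 e).

Both tables ship as plain-text package data (``data/form_factors.txt``,
``data/vdw_radii.txt``) so additional elements can be added without touching
code.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "CromerMannCoefficients",
    "supported_elements",
    "atomic_number",
    "form_factor",
    "vdw_radius",
    "combined_vdw",
    "UnsupportedElementError",
]


class UnsupportedElementError(KeyError):
    """Raised when an element symbol is absent from the packaged tables."""

    def __init__(self, element: str) -> None:
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return (
            f"element {self.element!r} is not in the packaged atomic tables; "
            f"supported: {', '.join(supported_elements())}"
        )


@dataclass(frozen=True)
class CromerMannCoefficients:
    """Analytic form-factor coefficient set for one element."""

    element: str
    z: int
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        s2 = (q / (4.0 * np.pi)) ** 2
        f = np.full_like(s2, self.c)
        for a_i, b_i in zip(self.a, self.b):
            f += a_i * np.exp(-b_i * s2)
        return f


def _data_lines(filename: str):
    text = resources.files("trxsim.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split()


@lru_cache(maxsize=1)
def _form_factor_table() -> dict[str, CromerMannCoefficients]:
    table: dict[str, CromerMannCoefficients] = {}
    for tok in _data_lines("form_factors.txt"):
        el, z, *rest = tok
        vals = [float(x) for x in rest]
        table[el] = CromerMannCoefficients(
            element=el,
            z=int(z),
            a=(vals[0], vals[2], vals[4], vals[6]),
            b=(vals[1], vals[3], vals[5], vals[7]),
            c=vals[8],
        )
    return table


@lru_cache(maxsize=1)
def _vdw_table() -> dict[str, float]:
    return {tok[0]: float(tok[1]) for tok in _data_lines("vdw_radii.txt")}


def supported_elements() -> tuple[str, ...]:
    """Element symbols present in both packaged tables, in Z order."""
    ff = _form_factor_table()
    common = [el for el in ff if el in _vdw_table()]
    return tuple(sorted(common, key=lambda el: ff[el].z))


def _lookup(table: dict, element: str):
    try:
        return table[element]
    except KeyError:
        raise UnsupportedElementError(element) from None


def atomic_number(element: str) -> int:
    """Number of electrons Z of the neutral atom."""
    return _lookup(_form_factor_table(), element).z


def form_factor(element: str, q: np.ndarray) -> np.ndarray:
    """Atomic X-ray form factor f(q) in electrons, on the given q grid (1/A).

    Parameters
    ----------
    element
        Element symbol (e.g. ``"I"``).
    q
        Momentum transfer values, 1/A, all >= 0.

    Returns
    -------
    numpy.ndarray aligned with ``q``; ``f(0)`` equals Z to within 0.1 e.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q values must be non-negative")
    return _lookup(_form_factor_table(), element)(q)


def vdw_radius(element: str) -> float:
    """van der Waals radius in Angstrom."""
    return _lookup(_vdw_table(), element)


def combined_vdw(element_i: str, element_j: str) -> float:
    """Hard-sphere contact distance V_ij = r_vdw(i) + r_vdw(j), in Angstrom.

    Symmetric in its arguments; used as the inner knot of the trapezoidal
    solute-solvent pair-distribution approximation.
    """
    return vdw_radius(element_i) + vdw_radius(element_j)
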
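"""Solvent-only (heating) difference term.

Energy deposited by the pump pulse relaxes into the bulk solvent and changes
its temperature and density; the resulting difference signal is the
contraction

    dS_solvent(q) = dT * (dS/dT)_rho(q) + drho * (dS/drho)_T(q),

with the two solvent differentials taken from the literature (or, here,
packaged synthetic stand-ins).  The maximum deposited heat per mole of
solvent assumes every excited molecule that does not enter a structural
channel returns its full photon energy as heat:

    Q_max = (h c / lambda) N_A * r_heat * c_excited / c_solv,

an upper bound by construction.  The isochoric and isobaric limits give the
maximum responses dT_max = Q_max / C_v and drho_max = -alpha_p (Q_max / C_p)
rho_0.  In time, dT holds at dT_max up to 10 ns then falls linearly to zero
by 3 us, while drho rises linearly from zero over the same window — the
standard fast-approximation for the acoustic/thermal crossover.

The packaged per-solvent differential curves are smooth damped oscillations,
synthetic stand-ins with literature-like amplitude and period; a loader
accepts user-supplied two-column literature curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import constants

from .cage import SolventComposition
from .debye import PER_SOLVENT, ScatteringCurve, require_same_grid

__all__ = [
    "SolventModel",
    "ThermalState",
    "max_heat",
    "max_temperature_rise",
    "max_density_change",
    "thermal_profile",
    "solvent_signal",
    "builtin_solvent",
    "builtin_solvent_names",
    "synthetic_dsdt",
    "synthetic_dsdrho",
    "load_differential_curve",
    "T_PLATEAU",
    "T_RELAXED",
]

T_PLATEAU = 10e-9  # s: dT stays at its maximum up to here
T_RELAXED = 3e-6   # s: dT has fully converted into drho by here


@dataclass(frozen=True)
class ThermalState:
    """Temperature change (K) and density change (g/mL) of the bulk solvent."""

    delta_t: float
    delta_rho: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_t) and np.isfinite(self.delta_rho)):
            raise ValueError("thermal state must be finite")


@dataclass(frozen=True)
class SolventModel:
    """Thermophysical constants plus the two differential scattering curves."""

    name: str
    concentration: float          # mol/L
    mass_density: float           # g/mL
    heat_capacity_v: float        # J/(mol K)
    heat_capacity_p: float        # J/(mol K)
    expansivity: float            # 1/K
    dsdt: ScatteringCurve         # (dS/dT)_rho, e.u. per solvent molecule per K
    dsdrho: ScatteringCurve       # (dS/drho)_T, e.u. per solvent molecule per (g/mL)
    composition: SolventComposition

    def __post_init__(self) -> None:
        for attr in ("concentration", "mass_density", "heat_capacity_v",
                     "heat_capacity_p", "expansivity"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        require_same_grid(self.dsdt, self.dsdrho)


def max_heat(pump_wavelength_nm: float, c_excited: float,
             r_heat: float, c_solv: float) -> float:
    """Upper-bound heat per mole of solvent, J/mol.

    ``c_excited`` is the molar concentration of excited solute (excitation
    fraction times solute concentration); ``r_heat`` the fraction of excited
    molecules that only release heat.
    """
    if pump_wavelength_nm <= 0:
        raise ValueError("pump wavelength must be positive")
    if not 0.0 <= r_heat <= 1.0:
        raise ValueError("r_heat must lie in [0, 1]")
    if c_excited < 0 or c_solv <= 0:
        raise ValueError("concentrations must be positive")
    photon_energy_molar = (
        constants.h * constants.c / (pump_wavelength_nm * 1e-9) * constants.N_A
    )
    return photon_energy_molar * r_heat * c_excited / c_solv


def max_temperature_rise(q_max: float, heat_capacity_v: float) -> float:
    """Isochoric limit: dT_max = Q_max / C_v, in K."""
    if heat_capacity_v <= 0:
        raise ValueError("C_v must be positive")
    return q_max / heat_capacity_v


def max_density_change(q_max: float, heat_capacity_p: float,
                       expansivity: float, mass_density: float) -> float:
    """Isobaric limit: drho_max = -alpha_p (Q_max / C_p) rho_0, in g/mL.

    Negative for any deposited heat: the solvent expands on isobaric heating.
    """
    if heat_capacity_p <= 0 or expansivity <= 0 or mass_density <= 0:
        raise ValueError("C_p, alpha_p and rho_0 must be positive")
    return -expansivity * (q_max / heat_capacity_p) * mass_density


def thermal_profile(t_delay: float, delta_t_max: float,
                    delta_rho_max: float) -> ThermalState:
    """Piecewise-linear time dependence of (dT, drho).

    Before time zero nothing has happened; up to 10 ns the response is purely
    isochoric (dT_max, 0); by 3 us it is purely isobaric (0, drho_max); in
    between both interpolate linearly in t.
    """
    if t_delay < 0:
        return ThermalState(0.0, 0.0)
    if t_delay <= T_PLATEAU:
        return ThermalState(delta_t_max, 0.0)
    if t_delay >= T_RELAXED:
        return ThermalState(0.0, delta_rho_max)
    x = (t_delay - T_PLATEAU) / (T_RELAXED - T_PLATEAU)
    return ThermalState((1.0 - x) * delta_t_max, x * delta_rho_max)


def solvent_signal(state: ThermalState, solvent: SolventModel) -> ScatteringCurve:
    """dS_solvent(q) = dT (dS/dT)_rho + drho (dS/drho)_T, e.u. per solvent molecule."""
    q = require_same_grid(solvent.dsdt, solvent.dsdrho)
    intensity = (
        state.delta_t * solvent.dsdt.intensity
        + state.delta_rho * solvent.dsdrho.intensity
    )
    return ScatteringCurve(q, intensity, normalization=PER_SOLVENT)


# ---------------------------------------------------------------------------
# Packaged solvents with synthetic differential curves
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _solvent_table() -> dict[str, dict]:
    text = resources.files("trxsim.data").joinpath("solvents.txt").read_text()
    table: dict[str, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, comp, rho, mm, cv, cp, alpha = line.split()
        composition = {
            el: int(n) for el, n in (pair.split(":") for pair in comp.split(","))
        }
        table[name] = {
            "composition": composition,
            "mass_density": float(rho),
            "molar_mass": float(mm),
            "heat_capacity_v": float(cv),
            "heat_capacity_p": float(cp),
            "expansivity": float(alpha),
        }
    return table


def builtin_solvent_names() -> tuple[str, ...]:
    return tuple(_solvent_table())


def synthetic_dsdt(q: np.ndarray, solvent_name: str = "cyclohexane") -> ScatteringCurve:
    """Synthetic stand-in for the literature (dS/dT)_rho curve.

    A damped oscillation with e.u.-per-K amplitude of order one and a first
    negative lobe near q ~ 1.5 1/A, qualitatively mimicking published solvent
    heating differentials.  It is *not* a measured curve.
    """
    q = np.asarray(q, dtype=float)
    period = 2.2 + 0.03 * (hash_offset(solvent_name) % 13)
    vals = -1.1 * np.sin(2.0 * np.pi * q / period) * np.exp(-q / 2.4)
    return ScatteringCurve(q, vals, normalization=PER_SOLVENT)


def synthetic_dsdrho(q: np.ndarray, solvent_name: str = "cyclohexane") -> ScatteringCurve:
    """Synthetic stand-in for the literature (dS/drho)_T curve (per g/mL)."""
    q = np.asarray(q, dtype=float)
    period = 2.6 + 0.02 * (hash_offset(solvent_name) % 17)
    vals = 95.0 * np.cos(2.0 * np.pi * q / period) * np.exp(-q / 1.8)
    return ScatteringCurve(q, vals, normalization=PER_SOLVENT)


def hash_offset(name: str) -> int:
    """Small deterministic per-name offset so packaged solvents differ slightly."""
    return sum(ord(ch) for ch in name)


def builtin_solvent(name: str, q: np.ndarray,
                    dsdt: ScatteringCurve | None = None,
                    dsdrho: ScatteringCurve | None = None) -> SolventModel:
    """Construct a packaged solvent on the given q grid.

    The differential curves default to the synthetic stand-ins; pass loaded
    literature curves to override them.
    """
    table = _solvent_table()
    if name not in table:
        raise KeyError(
            f"unknown solvent {name!r}; packaged: {', '.join(table)}"
        )
    entry = table[name]
    concentration = entry["mass_density"] / entry["molar_mass"] * 1000.0  # mol/L
    composition = SolventComposition.from_mass_density(
        entry["composition"], entry["mass_density"], entry["molar_mass"]
    )
    return SolventModel(
        name=name,
        concentration=concentration,
        mass_density=entry["mass_density"],
        heat_capacity_v=entry["heat_capacity_v"],
        heat_capacity_p=entry["heat_capacity_p"],
        expansivity=entry["expansivity"],
        dsdt=dsdt if dsdt is not None else synthetic_dsdt(q, name),
        dsdrho=dsdrho if dsdrho is not None else synthetic_dsdrho(q, name),
        composition=composition,
    )


def load_differential_curve(path) -> ScatteringCurve:
    """Load a user-supplied differential curve from two-column text (q, value)."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) < 2:
            raise ValueError(f"{path.name} line {lineno}: expected 'q value'")
        rows.append((float(tok[0]), float(tok[1])))
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    q = np.array([x for x, _ in rows])
    v = np.array([y for _, y in rows])
    return ScatteringCurve(q, v, normalization=PER_SOLVENT)
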
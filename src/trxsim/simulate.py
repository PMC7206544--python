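"""Signal assembly and time-resolved series simulation.

The simulated difference curve at one pump-probe delay is the sum of four
terms,

    dS_sim(q) = dS_solute(q) + dS_cage(q) + dS_solvent(q) + dS_noise(q),

all scaled to one mole of solvent.  Species populations evolve through a
general first-order rate network solved with the matrix exponential; the
population vector covers every species (including the recovered ground
state, which contributes nothing to the difference signal) and is conserved
exactly.

A :class:`SimulationPlan` distributes a total beam time over M delays with
equal measurement time per delay, so each delay accumulates
I = floor(f * (t_total * d / M) / 2) difference curves and its averaged noise
shrinks as 1/sqrt(I) — the trade-off between the number of delays and the
per-delay signal-to-noise ratio that the planning report tabulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import cage as cage_mod
from . import debye as debye_mod
from . import noise_model, solvent_heating
from .debye import PER_SOLVENT, ScatteringCurve
from .noise_model import BeamParameters, NoiseReference
from .solvent_heating import SolventModel
from .structures import MolecularStructure

__all__ = [
    "KineticScheme",
    "SimulationPlan",
    "SeriesResult",
    "populations_at",
    "simulate_components",
    "simulate_difference",
    "simulate_series",
    "plan_report",
]

logger = logging.getLogger(__name__)

DEFAULT_PUMP_WAVELENGTH_NM = 267.0  # typical UV pump used throughout the examples


@dataclass(frozen=True)
class KineticScheme:
    """First-order rate network over named species.

    ``species`` maps a name to the fragment tuple representing it; ``ground``
    names the reference (unexcited reactant) species.  ``initial_populations``
    are the post-excitation branching fractions of the *excited* population at
    t = 0+; any unassigned remainder starts in the ground state (prompt heat
    release without a structural channel).  ``rates`` holds first-order rate
    constants (1/s) keyed by (source, destination).
    """

    species: Mapping[str, tuple[MolecularStructure, ...]]
    ground: str
    initial_populations: Mapping[str, float]
    rates: Mapping[tuple[str, str], float] = field(default_factory=dict)
    excitation_fraction: float = 0.0

    def __post_init__(self) -> None:
        species = {
            name: debye_mod._as_fragments(frags)
            for name, frags in dict(self.species).items()
        }
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "initial_populations",
                           dict(self.initial_populations))
        object.__setattr__(self, "rates", dict(self.rates))
        if self.ground not in species:
            raise ValueError(f"ground species {self.ground!r} not in species map")
        total = 0.0
        for name, pop in self.initial_populations.items():
            if name not in species:
                raise ValueError(f"initial population for unknown species {name!r}")
            if pop < 0:
                raise ValueError("initial populations must be non-negative")
            total += pop
        if total > 1.0 + 1e-9:
            raise ValueError("initial populations must sum to at most 1")
        for (src, dst), k in self.rates.items():
            if src not in species or dst not in species:
                raise ValueError(f"rate {src!r}->{dst!r} references unknown species")
            if k < 0:
                raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.excitation_fraction <= 1.0:
            raise ValueError("excitation fraction must lie in [0, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.species)

    def heat_fraction(self) -> float:
        """Fraction of excited molecules with no structural channel (default r_heat)."""
        structural = sum(
            pop for name, pop in self.initial_populations.items()
            if name != self.ground
        )
        return max(0.0, 1.0 - structural)

    @classmethod
    def static_channel(cls, channel: debye_mod.ReactionChannel) -> "KineticScheme":
        """Freeze a single-delay reaction channel into a rate-free scheme."""
        species = {"reactant": channel.reactant}
        pops = {}
        for idx, (frags, frac) in enumerate(channel.products):
            name = f"product_{idx}"
            species[name] = frags
            pops[name] = frac
        return cls(
            species=species, ground="reactant", initial_populations=pops,
            rates={}, excitation_fraction=channel.excitation_fraction,
        )


def populations_at(scheme: KineticScheme, t_delay: float) -> dict[str, float]:
    """Species fractions of the excited population at a delay.

    Solves dP/dt = A P with the matrix exponential.  A negative delay returns
    the unperturbed system (everything in the ground state).  Fractions sum
    to one at every delay.
    """
    names = scheme.names
    if t_delay < 0:
        return {name: (1.0 if name == scheme.ground else 0.0) for name in names}
    index = {name: i for i, name in enumerate(names)}
    p0 = np.zeros(len(names))
    for name, pop in scheme.initial_populations.items():
        p0[index[name]] = pop
    p0[index[scheme.ground]] += 1.0 - p0.sum()
    if scheme.rates and t_delay > 0:
        a = np.zeros((len(names), len(names)))
        for (src, dst), k in scheme.rates.items():
            a[index[dst], index[src]] += k
            a[index[src], index[src]] -= k
        p = expm(a * t_delay) @ p0
    else:
        p = p0
    return dict(zip(names, p.tolist()))


def _species_library(
    scheme: KineticScheme, solvent: SolventModel, q: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-species (Debye, cage) intensities, computed once per run."""
    lib = {}
    for name, fragments in scheme.species.items():
        s_debye = debye_mod.species_intensity(fragments, q).intensity
        s_cage = cage_mod.species_cage_intensity(
            fragments, solvent.composition, q
        ).intensity
        lib[name] = (s_debye, s_cage)
    return lib


def simulate_components(
    scheme: KineticScheme,
    solvent: SolventModel,
    c_solu: float,
    t_delay: float,
    q: np.ndarray,
    pump_wavelength_nm: float = DEFAULT_PUMP_WAVELENGTH_NM,
    r_heat: Optional[float] = None,
    _library: Optional[dict] = None,
) -> dict[str, ScatteringCurve]:
    """The three deterministic signal components at one delay.

    Returns ``{"solute": ..., "cage": ..., "solvent": ...}``, each in e.u.
    per solvent molecule.
    """
    if c_solu <= 0:
        raise ValueError("solute concentration must be positive")
    q = np.asarray(q, dtype=float)
    lib = _library if _library is not None else _species_library(scheme, solvent, q)
    pops = populations_at(scheme, t_delay)
    s_r_debye, s_r_cage = lib[scheme.ground]
    scale = (c_solu / solvent.concentration) * scheme.excitation_fraction
    d_solute = np.zeros_like(q)
    d_cage = np.zeros_like(q)
    for name, pop in pops.items():
        s_debye, s_cage = lib[name]
        d_solute += pop * (s_debye - s_r_debye)
        d_cage += pop * (s_cage - s_r_cage)
    d_solute *= scale
    d_cage *= scale

    if r_heat is None:
        r_heat = scheme.heat_fraction()
    c_excited = scheme.excitation_fraction * c_solu
    q_max = solvent_heating.max_heat(
        pump_wavelength_nm, c_excited, r_heat, solvent.concentration
    )
    dt_max = solvent_heating.max_temperature_rise(q_max, solvent.heat_capacity_v)
    drho_max = solvent_heating.max_density_change(
        q_max, solvent.heat_capacity_p, solvent.expansivity, solvent.mass_density
    )
    state = solvent_heating.thermal_profile(t_delay, dt_max, drho_max)
    d_solvent = solvent_heating.solvent_signal(state, solvent)
    if not np.allclose(d_solvent.q, q):
        raise ValueError("solvent differential curves are not on the simulation q grid")
    return {
        "solute": ScatteringCurve(q, d_solute, normalization=PER_SOLVENT),
        "cage": ScatteringCurve(q, d_cage, normalization=PER_SOLVENT),
        "solvent": d_solvent,
    }


def simulate_difference(
    scheme: KineticScheme,
    solvent: SolventModel,
    c_solu: float,
    beam: BeamParameters,
    noise_ref: NoiseReference,
    t_delay: float,
    q: np.ndarray,
    seed: Optional[int] = None,
    noise: bool = True,
    pump_wavelength_nm: float = DEFAULT_PUMP_WAVELENGTH_NM,
    r_heat: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    _library: Optional[dict] = None,
) -> ScatteringCurve:
    """Full simulated difference curve at one delay (sum of the four terms).

    With ``noise=False`` the deterministic three-term sum is returned.  The
    attached per-point sigma is sigma_target / sqrt(I) for the beam's
    difference-curve count I.
    """
    q = np.asarray(q, dtype=float)
    comps = simulate_components(
        scheme, solvent, c_solu, t_delay, q,
        pump_wavelength_nm=pump_wavelength_nm, r_heat=r_heat, _library=_library,
    )
    total = sum(c.intensity for c in comps.values())
    sigma_target = noise_model.scale_sigma(noise_ref, beam)
    if not np.allclose(sigma_target.q, q):
        raise ValueError("noise reference is not on the simulation q grid")
    n_curves = noise_model.n_difference_curves(beam)
    sigma_avg = None
    if n_curves >= 1:
        sigma_avg = sigma_target.intensity / np.sqrt(n_curves)
    if noise:
        if n_curves < 1:
            raise ValueError(
                "beam parameters yield no difference curves; cannot add noise"
            )
        if rng is None and seed is None:
            raise ValueError("a seed (or generator) is required when noise is enabled")
        noise_curve = noise_model.generate_noise(
            sigma_target, n_curves, seed=seed, rng=rng
        )
        total = total + noise_curve.intensity
    return ScatteringCurve(q, total, sigma=sigma_avg, normalization=PER_SOLVENT)


@dataclass(frozen=True)
class SimulationPlan:
    """How a total beam time is split over time delays.

    Equal measurement time per delay (the default and only built-in
    allocation); ``beam`` carries f, D, n of the target beamline, while the
    per-delay accumulation time is ``total_time * duty_cycle / len(delays)``.
    """

    delays: tuple[float, ...]
    total_time: float
    duty_cycle: float
    beam: BeamParameters
    noise_ref: NoiseReference
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        delays = tuple(sorted(float(t) for t in self.delays))
        object.__setattr__(self, "delays", delays)
        if not delays:
            raise ValueError("at least one time delay is required")
        if self.total_time <= 0:
            raise ValueError("total beam time must be positive")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError("duty cycle must lie in (0, 1]")

    def per_delay_beam(self) -> BeamParameters:
        t_delay = self.total_time * self.duty_cycle / len(self.delays)
        return self.beam.replace(t=t_delay, d=1.0)


@dataclass(frozen=True)
class SeriesResult:
    """Curves per delay plus the bookkeeping needed for the planning report."""

    delays: tuple[float, ...]
    curves: tuple[ScatteringCurve, ...]
    noise_free: tuple[ScatteringCurve, ...]
    n_curves_per_delay: int
    sigma_per_curve: ScatteringCurve
    noise_enabled: bool = True


def simulate_series(
    plan: SimulationPlan,
    scheme: KineticScheme,
    solvent: SolventModel,
    c_solu: float,
    q: np.ndarray,
    noise: bool = True,
    pump_wavelength_nm: float = DEFAULT_PUMP_WAVELENGTH_NM,
    r_heat: Optional[float] = None,
) -> SeriesResult:
    """Simulate one difference curve per planned delay.

    Each delay consumes an equal slice of the usable beam time; its noise is
    drawn from an independent, seed-derived stream so the whole series is
    reproducible from ``plan.seed``.
    """
    q = np.asarray(q, dtype=float)
    per_delay_beam = plan.per_delay_beam()
    n_curves = noise_model.n_difference_curves(per_delay_beam)
    if noise and n_curves < 1:
        raise ValueError(
            f"allocation leaves no difference curves per delay "
            f"({len(plan.delays)} delays over {plan.total_time} s)"
        )
    if noise and plan.seed is None:
        raise ValueError("plan.seed is required when noise is enabled")
    sigma_target = noise_model.scale_sigma(plan.noise_ref, per_delay_beam)
    library = _species_library(scheme, solvent, q)
    curves = []
    noise_free = []
    for idx, t_delay in enumerate(plan.delays):
        clean = simulate_difference(
            scheme, solvent, c_solu, per_delay_beam, plan.noise_ref, t_delay, q,
            noise=False, pump_wavelength_nm=pump_wavelength_nm, r_heat=r_heat,
            _library=library,
        )
        noise_free.append(clean)
        if noise:
            rng = np.random.default_rng([plan.seed, idx])
            noise_curve = noise_model.generate_noise(sigma_target, n_curves, rng=rng)
            curves.append(clean.with_intensity(
                clean.intensity + noise_curve.intensity, sigma=clean.sigma
            ))
        else:
            curves.append(clean)
    return SeriesResult(
        delays=plan.delays,
        curves=tuple(curves),
        noise_free=tuple(noise_free),
        n_curves_per_delay=n_curves,
        sigma_per_curve=sigma_target,
        noise_enabled=noise,
    )


def plan_report(plan: SimulationPlan, series: SeriesResult) -> pd.DataFrame:
    """Per-delay planning table: delay, I, averaged noise level, peak signal, SNR.

    SNR is the artifact's convention: max |noise-free signal| over the median
    per-point averaged noise std.  Infinite when noise is disabled or zero.
    """
    n = series.n_curves_per_delay
    rows = []
    for t_delay, clean in zip(series.delays, series.noise_free):
        if series.noise_enabled and n >= 1:
            sigma_avg = np.median(series.sigma_per_curve.intensity) / np.sqrt(n)
        else:
            sigma_avg = 0.0
        peak = float(np.max(np.abs(clean.intensity)))
        snr = peak / sigma_avg if sigma_avg > 0 else float("inf")
        rows.append(
            {"delay_s": t_delay, "n_difference_curves": n,
             "sigma_avg": sigma_avg, "peak_signal": peak, "snr": snr}
        )
    return pd.DataFrame(rows)
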
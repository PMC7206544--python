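"""Photon-accounting noise model: sigma scaling by sqrt(N) and averaged noise.

The per-difference-curve noise level sigma(q) is taken from a reference
neat-solvent measurement and rescaled to the planned beamline by the
shot-noise law

    sigma_target(q) = sigma_ref(q) * sqrt(N_target / N_ref),
    N = f * D * n   (repetition rate x exposure per curve x photons/pulse),

the variance of a photon-counting measurement being proportional to the
number of incident photons.  Only this quantum (shot) noise is modelled —
systematic sources (jet thickness, pulse intensity drifts) are deliberately
excluded, so the estimate is an upper-bound convention for the uncorrelated
noise floor of the reference.

One laser-on/laser-off pulse pair yields one difference curve, so a run of
nominal length t at duty cycle d accumulates I = floor(f t d / 2) difference
curves; averaging I curves shrinks the noise by 1/sqrt(I).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .debye import PER_SOLVENT, ScatteringCurve

__all__ = [
    "BeamParameters",
    "NoiseReference",
    "photons_per_curve",
    "scale_sigma",
    "n_difference_curves",
    "generate_noise",
    "synthetic_sigma",
]

logger = logging.getLogger(__name__)

# Above this many total draws, generate_noise samples the (exactly equivalent)
# distribution of the I-curve mean directly instead of materialising I draws.
_DIRECT_DRAW_LIMIT = 20_000_000


@dataclass(frozen=True)
class BeamParameters:
    """Photon accounting inputs of one acquisition.

    f: repetition rate (Hz); D: detector exposure per curve (s); n: photons
    per pulse; t: nominal accumulation time (s); d: duty cycle in (0, 1].
    """

    f: float
    D: float
    n: float
    t: float = 1.0
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0 or self.D <= 0 or self.n <= 0:
            raise ValueError("f, D and n must be positive")
        if self.t < 0:
            raise ValueError("accumulation time must be non-negative")
        if not 0.0 < self.d <= 1.0:
            raise ValueError("duty cycle must lie in (0, 1]")

    def replace(self, **kwargs) -> "BeamParameters":
        fields = {"f": self.f, "D": self.D, "n": self.n, "t": self.t, "d": self.d}
        fields.update(kwargs)
        return BeamParameters(**fields)


@dataclass(frozen=True)
class NoiseReference:
    """A measured (or synthetic) sigma_solvent(q) with its acquisition parameters."""

    sigma: ScatteringCurve
    beam: BeamParameters

    def __post_init__(self) -> None:
        if np.any(self.sigma.intensity < 0):
            raise ValueError("reference sigma must be non-negative")


def photons_per_curve(beam: BeamParameters) -> float:
    """Incident photons contributing to one scattering curve: N = f * D * n."""
    return beam.f * beam.D * beam.n


def scale_sigma(ref: NoiseReference, target_beam: BeamParameters) -> ScatteringCurve:
    """Rescale the reference sigma to the target beamline: sigma * sqrt(N_t/N_ref)."""
    n_ref = photons_per_curve(ref.beam)
    if n_ref <= 0:
        raise ValueError("reference photon count must be positive")
    factor = math.sqrt(photons_per_curve(target_beam) / n_ref)
    return ScatteringCurve(
        ref.sigma.q, factor * ref.sigma.intensity,
        normalization=ref.sigma.normalization,
    )


def n_difference_curves(beam: BeamParameters) -> int:
    """Difference curves accumulated in the run: I = floor(f t d / 2).

    One difference curve consumes a laser-on/laser-off pulse pair.  Returns 0
    (with a warning) when the run is too short for a single pair.
    """
    count = math.floor(beam.f * beam.t * beam.d / 2.0)
    if count == 0:
        logger.warning(
            "beam parameters yield zero difference curves (f=%g Hz, t=%g s, d=%g)",
            beam.f, beam.t, beam.d,
        )
    return count


def generate_noise(
    sigma_target: ScatteringCurve, n_curves: int,
    seed: Optional[int] = None, rng: Optional[np.random.Generator] = None,
) -> ScatteringCurve:
    """Average of ``n_curves`` Gaussian noise curves, one value per q point.

    Each underlying curve draws independently from Normal(0, sigma_target(q));
    the averaged result has pointwise standard deviation sigma_target/sqrt(I).
    For very large I the mean is sampled from its exact sampling distribution
    Normal(0, sigma/sqrt(I)) directly rather than materialising I draws.
    Reproducible for a fixed seed.
    """
    if n_curves < 1:
        raise ValueError("need at least one difference curve to generate noise")
    if rng is None:
        rng = np.random.default_rng(seed)
        logger.debug("generate_noise: seed=%s, I=%d", seed, n_curves)
    sigma = sigma_target.intensity
    n_q = sigma.size
    if n_curves * n_q <= _DIRECT_DRAW_LIMIT:
        draws = rng.standard_normal((n_curves, n_q)) * sigma[None, :]
        noise = draws.mean(axis=0)
    else:
        noise = rng.standard_normal(n_q) * (sigma / math.sqrt(n_curves))
    return ScatteringCurve(
        sigma_target.q, noise, normalization=sigma_target.normalization
    )


def synthetic_sigma(
    level: float, q: np.ndarray, beam: Optional[BeamParameters] = None,
    shape: str = "solvent_like",
) -> NoiseReference:
    """Synthetic smooth reference sigma(q), stand-in for a measured solvent noise curve.

    ``level`` sets the overall amplitude (e.u. per difference curve);
    ``shape`` is ``"flat"`` (sigma = level everywhere) or ``"solvent_like"``
    (a smooth bump near the solvent diffraction peak, strictly positive).
    The attached BeamParameters default to a synchrotron-like acquisition.
    """
    if level <= 0:
        raise ValueError("sigma level must be positive")
    q = np.asarray(q, dtype=float)
    if beam is None:
        beam = BeamParameters(f=1.0e3, D=1.5, n=5.0e8, t=1.0, d=1.0)
    if shape == "flat":
        vals = np.full_like(q, level)
    elif shape == "solvent_like":
        vals = level * (0.4 + np.exp(-((q - 1.4) ** 2) / (2 * 0.45**2))
                        + 0.1 * q / (1.0 + q))
    else:
        raise ValueError(f"unknown sigma shape {shape!r}")
    curve = ScatteringCurve(q, vals, normalization=PER_SOLVENT)
    return NoiseReference(sigma=curve, beam=beam)
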
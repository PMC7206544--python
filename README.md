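# trxsim

A feasibility simulator for **time-resolved X-ray solution scattering**
(TRXL / TRXSS) experiments.  Given a photoreaction (reactant and product
structures, branching fractions, excitation ratio), a solvent and a set of
beamline parameters, `trxsim` computes the four components of the pump-probe
difference scattering signal and assembles time-delay series with realistic
signal-to-noise — so that beam time can be planned before it is granted.

## Who it is for

Experimentalists preparing TRXL proposals at synchrotrons or XFELs who need
to answer, at the desk: *will the structural signal of my reaction rise above
the noise floor of this beamline, for this number of time delays, in this
much beam time?*

## The model

The simulated difference curve at a pump-probe delay *t* is

```
ΔS_sim(q) = ΔS_solute(q) + ΔS_cage(q) + ΔS_solvent(q) + ΔS_noise(q)
```

all in electron units (e.u.) per solvent molecule.

* **Solute-only term** — Debye scattering of randomly oriented molecules,
  `S(q) = Σ_m Σ_n f_m(q) f_n(q) sin(q r_nm)/(q r_nm)`, with Cromer–Mann
  atomic form factors; the difference is
  `(c_solu/c_solv) · r_exc · [Σ_p x_p S_p(q) − S_r(q)]`.
* **Solute–solvent cage term** — sine Fourier transform of solute–solvent
  pair-distribution functions.  Instead of molecular dynamics, each g_ij(r)
  is a trapezoid: zero inside the van der Waals contact V_ij, unity beyond
  V_ij + R_s (R_s the unweighted RMS molecular radius), linear in between.
  Externally computed RDFs can be supplied instead.
* **Solvent heating term** —
  `ΔS_solvent(q) = ΔT·(δS/δT)_ρ(q) + Δρ·(δS/δρ)_T(q)`, with the maximum
  responses from an upper-bound energy deposition
  `Q_max = (hc/λ) N_A r_heat c_exc/c_solv`, ΔT_max = Q_max/C_v and
  Δρ_max = −α_p (Q_max/C_p) ρ₀; ΔT holds until 10 ns then converts linearly
  into Δρ by 3 µs.
* **Noise term** — per-curve σ(q) taken from a reference neat-solvent
  measurement, rescaled between beamlines by the shot-noise law
  `σ ∝ √N` with `N = f·D·n` photons per curve; a run of length *t* at duty
  cycle *d* averages `I = ⌊f·t·d/2⌋` on/off difference curves, shrinking the
  noise by 1/√I.

Species populations evolve through a general first-order rate network solved
with the matrix exponential.

## Worked example

Iodoform (CHI₃) photolysis in cyclohexane at a 100 ps delay — 10 mM solute,
30 % excitation, branching 40:60 into the iso-CHI₂I–I isomer and the
CHI₂ + I radical pair:

```python
import numpy as np
from trxsim import (BeamParameters, builtin_solvent, default_q_grid,
                    n_difference_curves, synthetic_sigma, simulate_components)
from trxsim.simulate import KineticScheme
from trxsim.structures import build_fixture

q = default_q_grid()                       # 0.3–8.0 1/Å
scheme = KineticScheme(
    species={"reactant": (build_fixture("chi3"),),
             "isomer": (build_fixture("chi2i"),),
             "radical": (build_fixture("chi2"), build_fixture("i_atom"))},
    ground="reactant",
    initial_populations={"isomer": 0.4, "radical": 0.6},
    excitation_fraction=0.3,
)
solvent = builtin_solvent("cyclohexane", q)
comps = simulate_components(scheme, solvent, c_solu=0.01,
                            t_delay=100e-12, q=q, r_heat=0.3)
for name, curve in comps.items():
    print(f"{name:8s} peak |dS| = {np.max(np.abs(curve.intensity)):.4f} e.u.")

beam = BeamParameters(f=1e3, D=1.5, n=5e8, t=36.0, d=1.0)
print("difference curves in 36 s:", n_difference_curves(beam))
ref = noise = synthetic_sigma(0.5, q, beam=beam)
print(f"averaged noise level: "
      f"{np.median(ref.sigma.intensity)/np.sqrt(n_difference_curves(beam)):.5f} e.u.")
```

prints

```
solute   peak |dS| = 1.8028 e.u.
cage     peak |dS| = 0.4854 e.u.
solvent  peak |dS| = 0.3276 e.u.
difference curves in 36 s: 18000
averaged noise level: 0.00181 e.u.
```

The solute term dominates (heavy iodine atoms), the hard-sphere cage term is
a few-tenths-e.u. correction, the heating term is small in cyclohexane, and
after averaging 18 000 difference curves the noise floor sits two to three
orders of magnitude below the peak signal — this experiment is comfortably
feasible at a 1 kHz synchrotron beamline.

## Command line

```sh
trxsim fixtures --out fixtures --seed 7     # toy geometries, noise refs, demo configs
trxsim components --config fixtures/demo_chi3_single.toml   # four terms + sum
trxsim simulate   --config fixtures/demo_chi3_single.toml   # total per delay
trxsim series     --config fixtures/demo_chi3_series.toml   # delay series + manifest
trxsim plan       --config fixtures/demo_ab_plan.toml       # per-delay SNR table
```

One TOML file fully determines a run; all curve files carry `#` headers with
units, normalization and generation parameters, and any run with noise
enabled requires an explicit seed and is byte-for-byte reproducible.

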
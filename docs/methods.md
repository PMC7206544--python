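# Methods

This note records the scientific model implemented by `trxsim`, the choices
made where the design was genuinely open, and what the synthetic inputs do
and do not represent.

## Signal model

The simulated pump-probe difference curve at momentum transfer q (1/Å) and
delay t is the sum of four terms, each scaled to one mole of solvent
molecules and expressed in electron units (e.u.):

    ΔS_sim(q; t) = ΔS_solute + ΔS_cage + ΔS_solvent + ΔS_noise.

### Solute-only term

Species intensities come from the Debye equation over all atom pairs,
including the m = n self terms, so S(0) = (Σ Z)².  Form factors are the
analytic Cromer–Mann four-Gaussian sets (International Tables vol. C
convention, s = q/4π), shipped as plain-text data for H, C, N, O, F, S, Cl,
Fe, Br, Ru, I, Pt.  Because no specific form-factor tabulation is canonical
for this kind of simulator, correctness is asserted through physical
tolerances (|f(0) − Z| ≤ 0.1 e) rather than bit-matching any one table.

Multi-fragment products (e.g. a radical pair after dissociation) contribute
the sum of their fragments' intensities without interference cross terms:
fragments are assumed uncorrelated once the solvent cage separates them.
For isomerizations the self terms cancel in the difference; for
dissociations they do not, and they are retained.

### Cage term

The solute–solvent cross term of one solute molecule is

    S_cage(q) = Σ_i Σ_j f_i f_j N_i n_j ∫ 4π r² [g_ij(r) − 1] sinc(qr) dr,

with N_i the count of solute atoms of element i and n_j the bulk number
density (1/ų) of solvent atoms of element j.  Expressing the normalisation
through the bulk number density (rather than a simulation-box volume) makes
the term box-independent and consistent with per-solute-molecule units.

The hard-sphere g_ij(r) is a trapezoid: 0 below the van der Waals contact
V_ij (Bondi radii; 2.05 Å for the transition metals), 1 beyond V_ij + R_s,
linear in between.  R_s is the *unweighted* RMS distance of solute atoms
from the unweighted centroid — the radius-of-gyration formula with unit
weights, measuring spatial extent rather than mass.  The whole-molecule R_s
is used for every element pair of a species; fragments of a dissociated
product each use their own R_s.

Numerics: the transform integrand has compact support (g − 1 vanishes beyond
V_ij + R_s) and slope discontinuities at the two knots.  Integration is
trapezoidal on a knot-aligned grid with 0.0025 Å step plus a 1 Å guard
segment; with knots exactly on the grid the rule keeps O(h²) accuracy and
agrees with adaptive quadrature to better than 10⁻⁶ of the curve scale.
Externally computed RDFs (two-column text) are integrated on their own grid
with the g − 1 tail beyond the last tabulated r taken as zero.

Intramolecular solvent (j–j′) correlations are excluded by construction: the
cage term is solute–solvent only.  The hard-sphere approximation reproduces
only the coarse shape of an MD-derived cage term; it is intended for
signal-level estimates, not lineshape analysis, and nothing in the package
asserts agreement with MD beyond that.

### Solvent heating term

ΔS_solvent(q) = ΔT·(δS/δT)_ρ(q) + Δρ·(δS/δρ)_T(q).  The deposited heat is
the upper bound Q_max = (hc/λ)·N_A·r_heat·c_exc/c_solv (J per mole of
solvent): every excited molecule that does not enter a structural channel is
assumed to return its full photon energy as heat.  The isochoric and
isobaric limits give ΔT_max = Q_max/C_v and Δρ_max = −α_p (Q_max/C_p) ρ₀.
Note that with ρ₀ in g/mL this Δρ is an absolute density change in g/mL;
the packaged (δS/δρ)_T curves are defined per that same unit, so the
contraction is consistent.  In time, ΔT holds at ΔT_max up to 10 ns and
falls linearly (in t, not log t) to zero by 3 µs while Δρ rises linearly
from zero over the same window; negative delays are unperturbed.  This
piecewise-linear profile is the standard fast approximation to the
thermal-expansion crossover and deliberately avoids pathway-resolved
thermodynamics.

r_heat defaults to the fraction of excited molecules not assigned to a
structural channel at t = 0⁺, and can be overridden per run.

### Noise term

Only quantum (shot) noise is modelled.  A reference neat-solvent noise curve
σ(q) — per difference curve — carries its acquisition parameters (f, D, n);
scaling to another beamline uses σ ∝ √N with N = f·D·n photons per curve.
One laser-on/off pulse pair yields one difference curve, so a nominal
accumulation t at duty cycle d gives I = ⌊f·t·d/2⌋ curves, and the averaged
noise per q-point is Normal(0, σ/√I) with independent q-bins.  Systematic
noise (jet thickness, pulse-intensity drift, correlated q-bins) is
intentionally not modelled; because measured σ references contain it, the
estimate acts as an upper bound on the uncorrelated noise floor.

For I·n_q ≤ 2×10⁷ the averaged noise is computed literally as the mean of I
Gaussian draws; beyond that the mean is sampled from its exact sampling
distribution Normal(0, σ/√I) directly, which is the same law and keeps
10⁷-curve scenarios desk-scale.  Every stochastic operation takes an
explicit seed (numpy `default_rng`), and series runs derive one independent
stream per delay from the plan seed, so outputs are byte-reproducible.

### Kinetics and assembly

Populations evolve through a general first-order network dP/dt = AP solved
with the matrix exponential; the vector covers all species including the
recovered ground state, and the column-sum-zero generator conserves total
population to machine precision.  The difference signal at delay t uses the
instantaneous populations as channel weights against the ground-state
reference, so recovered molecules contribute zero automatically.

A `SimulationPlan` divides the usable time t_total·d equally over M delays
(the only built-in allocation); the per-delay SNR in the planning table is
max |noise-free ΔS| over the median per-point averaged noise std — an
artifact convention chosen for robustness, not a standard of the field.

## Synthetic inputs

The package must run offline, so all reference inputs ship as synthetic,
clearly labelled stand-ins:

* **Geometries** — the CHI₃/CHI₂I/CHI₂+I set is hand-built from standard
  bond lengths; cyclohexane and cis/trans azobenzene are RDKit ETKDG
  embeddings (fixed seed) with MMFF relaxation; 4,4′-dibromoazobenzene is
  built from azobenzene by substituting the two para hydrogens with bromine
  at 1.89 Å, leaving all other atoms untouched so that signal differences
  isolate the heavy-atom effect.  None of these claim to match refined
  experimental structures.
* **Solvent constants** — nominal literature values near 25 °C (density,
  molar mass, C_v, C_p, α_p) for seven common TRXL solvents; adequate for
  signal-level planning, not calorimetry.
* **Differential curves** — (δS/δT)_ρ and (δS/δρ)_T are smooth damped
  oscillations with literature-like amplitude (order 1 e.u./K and
  order 100 e.u. per g/mL) and slightly different periods per solvent.  They
  reproduce the magnitude and oscillatory character of published curves, not
  their actual shapes; users with literature curves load them from
  two-column text and they take precedence.
* **Noise references** — smooth, strictly positive σ(q) shapes with a bump
  near the solvent diffraction peak, at 0.5 e.u. per difference curve for a
  synchrotron-like acquisition (f = 1 kHz, D = 1.5 s, n = 5×10⁸) and scaled
  to the 30 Hz / 1 MHz XFEL presets by the √N law.  XFEL presets use
  shot-by-shot readout (D = 1/f), making n the photons per curve.

Consequently, passing tests demonstrate the correctness of the *machinery*
(transforms, scaling laws, assembly, determinism) on inputs with realistic
structure and magnitude; they do not validate any specific beamline's noise
floor or any solvent's true differentials.  Feeding measured references is
the intended path for quantitative proposals.

## Default parameters

| parameter | default | why |
| --- | --- | --- |
| q grid | 0.3–8.0 Å⁻¹, 0.01 Å⁻¹ step | covers the usual TRXL display range |
| pump wavelength | 267 nm | typical UV pump in the demo scenarios |
| r-integration step (cage) | 0.0025 Å, knot-aligned | ≤1e−6 relative quadrature error |
| noise draw cap | 2×10⁷ draws | literal averaging below, exact law above |
| ΔT plateau / relax times | 10 ns / 3 µs | fast-approximation thermal profile |
| demo solute | 10 mM CHI₃, 30 % excitation, 40:60 isomer:radical | representative heavy-atom photolysis |
| demo kinetic rates | isomer→ground 3.3×10⁶ s⁻¹, radical→ground 2×10⁵ s⁻¹ | illustrative, editable in the config |

## Degenerate inputs and tie-breaks

Single atoms have R_s = 0, degenerating the trapezoid to a step at V_ij.
sinc is evaluated through `np.sinc`, exact at qr = 0.  A plan whose
allocation leaves zero pulse pairs per delay is an error when noise is
requested and a logged warning otherwise.  Negative delays return the
unperturbed system everywhere (zero signal, noise only).  Branching
fractions must sum to 1 within 1e−9; populations are conserved within
1e−10 at every evaluated delay.

## Known limitations

No anomalous/ionic form factors, no Compton background, no orientational
anisotropy, no instrument-response convolution in time, no detector geometry
or azimuthal-integration corrections, no systematic-noise model, and no MD:
the cage term is either the trapezoid approximation or a user-supplied RDF.
The heating profile is a two-knot linear approximation, not an acoustic
model.  These are scope decisions, not oversights: the tool estimates
signal-to-noise feasibility, not publication-grade theoretical curves.
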
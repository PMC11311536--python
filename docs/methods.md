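# Methods

This note documents the models, parameter choices and numerical methods
behind `driftchem`, and what the synthetic test bed does and does not
establish about real data.

## Trajectory-method collision cross section

### Model

The ion is a rigid set of atoms with fixed partial charges (in real use,
electrostatic-potential-fitted charges from quantum chemistry). The buffer
gas is a rigid three-site nitrogen molecule with the TraPPE
parameterization: two nitrogen sites 1.10 Å apart carrying −0.482 e each
(ε/k_B = 36 K, σ = 3.31 Å) and a massless central site carrying +0.964 e,
which together reproduce the N₂ quadrupole moment. The ion–gas potential is

    V = Σ_{i,j} 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶] + k_e q_i q_j / r_ij

with Lorentz–Berthelot combination (geometric ε, arithmetic σ) between
per-element ion LJ parameters (UFF-derived defaults, user-overridable) and
the gas sites. Induced-dipole (polarization) terms are omitted: for
singly- and doubly-charged drug-sized ions in N₂ the dominant attractive
term at these temperatures is charge–quadrupole, and leaving polarization
out keeps the potential fully auditable from the two parameter tables. The
gas orientation is drawn uniformly per trajectory and frozen during it
(standard practice; N₂ rotation is fast compared to a collision only in
the opposite limit, but the orientation average is what the collision
integral needs).

### Estimator

The temperature-averaged momentum-transfer collision integral

    Ω⁽¹·¹⁾(T) = ½ ∫ x² e⁻ˣ Q⁽¹⁾(x kT) dx,  x = E/kT

is sampled with a three-way stratification: collision energies on the
quantiles of the Gamma(3) law x²e⁻ˣ/2 (via a 4096-point inverse-CDF
table), impact parameters uniform in b² within each energy stratum, and
fresh uniform random ion/gas orientations per trajectory. Each of
`n_orientation_samples` sweeps covers the full
`n_velocity_samples` × `n_impact_samples` grid; the reported standard
error is the standard deviation of the sweep means over √n_sweeps.
Defaults (16 × 150 × 20 = 48 000 trajectories) give ≲0.2 % standard error
for small neutral systems and a few percent for charged bead chains; a
60-atom structure completes in about a minute on one CPU core. Sample
counts trade accuracy for time linearly and are entirely the user's
choice.

The maximum impact parameter is found per energy stratum by a
grow/shrink search (factor 1.2) for the smallest b at which the largest
deflection over 8 random orientations falls below 10⁻³ rad, probed at the
stratum-centre energy. Making b_max energy-dependent matters for charged
ions: the long-range charge–quadrupole tail deflects slow collisions at
impact parameters where fast ones pass straight, and sampling every
energy out to the low-energy b_max would waste most trajectories and
inflate the variance several-fold.

### Integrator

Trajectories integrate the relative motion (reduced mass μ) with
classical RK4 and an adaptive step dt = η·d_min/(|v| + g), where d_min is
the distance to the nearest ion atom and g the asymptotic speed (the +g
keeps steps small at turning points where |v| → 0); η defaults to 0.015.
Trajectories start and end where the potential magnitude is below
10⁻⁴ kJ/mol (found by numeric scan over orientations, so charge–multipole
tails push the start distance out automatically). Energy drift beyond
10⁻⁴ (relative to the collision energy) triggers a retry at η/4 and η/16;
a still-failing trajectory is resampled and counted in the result's
`n_failed` diagnostic.

### Verification

Three independent checks anchor the engine (see the test suite):

* a steep inverse-power wall (r⁻²⁰⁰, prefactor e^{ψ(3)}kT chosen so the
  thermal average of the finite-exponent softness cancels at first order)
  reproduces the hard-sphere integral πd² within 1 %;
* for spherically symmetric systems the Monte-Carlo result agrees within
  2 % with `driftchem.oracle`, a quadrature implementation of the
  classical deflection-angle integral that shares no code with the
  trajectory engine. Its regression anchor, Ω⁽¹·¹⁾ = 32.4934 Å² for
  LJ(ε = 0.5 kJ/mol, σ = 3.5 Å) at 298 K, was computed once by the same
  quadrature at 10× resolution (120 energy nodes, 2400 b nodes, 2000
  angular nodes) and frozen;
* rigid rotations/translations of the input change results only within
  Monte-Carlo error, and zeroing all partial charges never increases the
  CCS (the attractive electrostatic term only enlarges it).

In the oracle, classical orbiting (near-degenerate outermost turning
point) is handled by replacing 1 − cos χ with its random-phase average 1;
at the reduced temperatures tested (kT/ε ≈ 5) this affects only a
negligible low-energy tail.

The projection approximation uses collision radii
2^{1/6}σ_atom/2 + r_gas (r_gas = 1.86 Å for N₂) and estimates the
orientation-averaged shadow area by rejection sampling with binomial
standard errors. It serves as the cheap companion for synthetic-data
generation and sanity checks, not as a substitute for the trajectory
method.

## Drift-tube conversions and peak picking

The single-field Mason–Schamp chain uses the standard-state number density
N₀ = 2.686781·10²⁵ m⁻³ and treats drift length and voltage as instrument
configuration (defaults 78.1 cm, 1570 V — typical for the commercial
instrument class; they are not printed quantities and all round-trip
identities are independent of them). The drift-region temperature defaults
to 300.0 K (the instruments of interest report 26–27.25 °C) and the
pressure to 3.94 Torr; both are configurable, with plausibility bounds
0.5–20 Torr and 200–400 K. A constant non-drift residence time t₀
(default 0) can be subtracted. Experimental CCS values quoted from vendor
single-field calibrations are treated as given inputs — the exact vendor
calibration conditions are not recoverable, so the pipeline never
recomputes published CCS values from raw drift times.

Peak picking finds local maxima above a relative-intensity threshold and a
minimum separation, refines each by a Gaussian fit over a ±FWHM window,
merges centroids that collapse within the minimum separation, and
annotates each peak with its Mason–Schamp CCS. Asymmetric (non-Gaussian)
peak shapes are out of scope.

## Assignment

The narrative practice of matching mobility peaks to computed structures is
formalized as *energy-first within a CCS gate*: candidates whose
calculated CCS is within `bias_threshold` percent (default 3.0, just above
the ≈2.8 % worst case reported for trajectory-method-vs-drift-tube
comparisons of drug-sized ions) of the peak's experimental CCS are
eligible; the eligible candidate with the lowest Gibbs energy wins, with
ties broken by smaller bias and then lexicographic id (deterministic).
Solution-phase energies rank candidates for electrospray-like data
(thermodynamically controlled protonation); gas-phase energies for
APCI-like data (kinetically controlled). One candidate may serve several
peaks; such candidates are flagged in the report. Boltzmann weights over
the ensemble report equilibrium populations at the ensemble temperature.

## pKa and speciation

The deprotonation free energy uses G_aq(H⁺) = −1111.27 kJ/mol. The
literature prints this constant as a positive magnitude (265.6 kcal/mol);
the thermodynamic cycle requires the negative aqueous proton free energy,
and the engine fixes the sign internally — the one sign convention in the
package a user cannot get wrong from the inputs. T defaults to 298.15 K;
the difference from 298 K is < 0.01 pKa units. Monoprotic compounds are
handled as degenerate diprotic systems (an extreme pKa1 such as −7.31
simply drives α_MH2 to numerical zero); the fractions are evaluated as a
log-space softmax, exact and overflow-safe over any pH range. Speciation
curves are *qualitative* predictors of electrospray charge-state
distributions only: the effective pH inside evaporating droplets is
unknown, so the pipeline reports a dication-expected flag at a user pH
rather than predicted intensities. Microstate (per-protomer) pKa
bookkeeping is out of scope: the most stable conformer per charge state
enters the cycle.

## Synthetic data

`make_bead_molecule` grows self-avoiding chains of a synthetic element
("X", 40 u, ε = 0.5 kJ/mol, σ = 3.4 Å) with integer charges on
well-separated beads; `extended` mode biases bond directions into a
forward cone, `compact` draws them uniformly. Bead chains replace real
drug geometries deliberately: the pipeline's correctness does not depend
on CCS realism, and no real geometries are available at desk scale.

`make_scenario` plants every quantity downstream stages must recover:
conformer ensembles with controlled solution-energy gaps (default uniform
2–8 kJ/mol, emulating the few-kJ/mol spreads of computed drug conformer
ensembles), true CCS values on an analytic ladder (base 150 Å², spacing
6 Å² — a few percent, like resolved protomer/conformer pairs), Gaussian
noise of 0.5 Å² on the *calculated* CCS to mimic method error, drift
spectra with one Gaussian peak per protomer (amplitude ∝ Boltzmann
population, 2 % FWHM, additive Gaussian noise at SNR 100 — the regime of
intense m/z-selected standards, where even minor-protomer peaks are
clearly visible), and thermochemistry obtained by inverting the pKa cycle
exactly. The truth record (JSON) names the generating candidate, amplitude
and detectability of every peak, and flags configurations the pipeline
cannot be expected to resolve (peaks closer than one FWHM, CCS spacing
below 3× the planted noise).

What passing synthetic tests shows: the inference chain — peak detection,
CCS conversion, gating, energy ranking, cycle inversion — is correct and
seed-stable under the stated noise model. What it does not show: that any
particular force-field or quantum-chemistry input is accurate, that real
peak shapes are Gaussian, or that the N₂ parameters match a specific
external trajectory-method code. Accordingly, no test asserts agreement
with published per-conformer CCS values; published numbers enter only as
typed reference pairs for arithmetic regression checks.

## Design choices that were genuinely open

* **File dialect.** Quantum-chemistry outputs arrive in vendor formats;
  the package defines a minimal extended-XYZ dialect (key=value comment
  line, fifth column for charge) that any such output converts to in a
  few lines, instead of parsing vendor files.
* **LJ defaults.** A (ε, σ) table per element is required by the LJ(12,6)
  engine; the UFF van-der-Waals set is used because it covers the periodic
  table uniformly and maps directly onto LJ(12,6), unlike buffered-14-7
  force-field sets. Users doing quantitative work should substitute
  parameters calibrated for N₂ CCS.
* **Monte-Carlo scheme.** Full stratified MC (energies × impact
  parameters × orientations) instead of nested quadrature: it yields an
  honest, single-number standard error and parallelizes trivially, at the
  cost of needing variance-reduction care (per-energy b_max) for charged
  ions.
* **Assignment formalization.** The gate-then-rank rule reproduces every
  published pairing in the reference set; alternatives (bias-first, or
  joint scoring) were rejected because the published reasoning is
  explicitly energetic once CCS agreement is plausible.

## Known limitations

* The reported lower end of published bias ranges (≈0.7 %) is not
  asserted anywhere: some published pairs give smaller biases (0.06 %),
  so only the upper bound is a meaningful invariant.
* Calculated pKa2 values of this cycle run ≈2 units above older
  literature values for the same drugs; the discrepancy is methodological
  (different cycles and different assigned protonation sites) and is not
  adjudicated here.
* The trajectory engine's absolute accuracy for real molecules is bounded
  by the generic LJ table and the omitted polarization term; its
  *internal* consistency (oracle agreement, limits, invariances) is what
  the test suite establishes.
* Arrival-time distributions are modeled as Gaussian; multiplexed or
  demultiplexed waveforms and asymmetric peaks are out of scope.
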
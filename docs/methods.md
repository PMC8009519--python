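# Methods

## The model

`hpfsurf` simulates a polarity-inverted surfactant — a rigid, compact
adamantyl head attached to a floppy triethylene-glycol (TEG) tail capped by
a hydroxyl group, referred to throughout as ADOH — in water and in
cyclohexane, using hybrid particle-field molecular dynamics (hPF-MD).

The molecule is mapped onto a linear five-bead chain A–E–E–E–T (A =
adamantyl C10H15, E = one CH2CH2O repeat, T = OH).  Cyclohexane is one
bead per molecule (C); one water bead lumps four molecules (W).

Nonbonded interactions are not pairwise.  Each species i has a number
density phi_i(r) evaluated on a cubic mesh, and the interaction energy is
the density functional

    W = sum_cells v_cell/phi0 [ 1/2 sum_ij chi_ij phi_i phi_j
                                + (1/(2 kappa)) (sum_i phi_i - phi0)^2 ]

with phi0 the mean total bead density.  Its density derivative is an
external potential per species,

    V_i(r) = 1/phi0 [ sum_j chi_ij phi_j(r) + (1/kappa)(phi_tot(r) - phi0) ],

and particles feel F = -grad V_i.  The chi matrix (kJ/mol) encodes the
chemistry; its single large entry chi(A,W) = 33.75 drives the hydrophobic
collapse of the adamantyl heads in water, while chi(A,C) = 0 makes
cyclohexane a good solvent for the head.

Bonds are harmonic, k_b = 1250 kJ/mol/nm^2 with rest lengths 0.33 nm (A–E)
and 0.28 nm (E–E, E–T), and there are no angle terms: the TEG tail is
deliberately a fully flexible chain, which is the physically relevant
regime for this surfactant.  These bonded constants are configurable; they
set the intramolecular length scale but equilibrium aggregation structure
is dominated by the field terms.

For cyclohexane systems the four tail beads can carry alternating partial
charges +0.4/-0.4 e (the molecule stays neutral), screened by a relative
dielectric constant eps_r = 5.  This mimics the quadrupolar glycol-ether
charge distribution whose weak electrostatics mediates the residual
clustering of the surfactant in the apolar solvent.

## Numerical scheme

* **Density assignment.** Cloud-in-cell (trilinear) weights onto cell
  centers; the weights are a partition of unity, so species counts are
  conserved to round-off.
* **Field forces.** The force is the exact negative gradient of the
  CIC-discretised energy, F_p = -sum_c V_i(c) grad w_c(x_p) — the analytic
  gradient of the trilinearly interpolated potential.  This makes mesh
  forces and energy mutually consistent to machine precision; the test
  suite pins this with central finite-difference oracles (delta = 1e-4 nm,
  relative tolerance 1e-4).
* **Mesh resolution.** Default cell edge ~0.5 nm (mesh = round(L/0.5)),
  i.e. the bead-radius scale.  This is a deliberate choice: with ~1 nm
  cells two surfactant molecules can sit on top of each other inside one
  cell at almost no energy cost, and the center-of-mass pair correlation
  develops an unphysical contact pile-up instead of a first-neighbor peak.
  At 0.5 nm the compressibility term resolves the intermolecular
  correlation hole and the ADOH–ADOH g(r) shows a first maximum near
  0.75 nm, the expected dimer contact distance.
* **Compressibility.** 1/kappa = 5 kJ/mol by default (configurable), in
  the range used across the hPF literature; larger values stiffen the
  total-density constraint.
* **Electrostatics.** Charges are spread with the same CIC kernel; the
  periodic Poisson equation is solved spectrally (continuum Green's
  function 4 pi k_C/(eps_r k^2), zero-mean potential); the field is
  differenced on the mesh (2-point central, periodic) and interpolated
  back with CIC.  Identical spread/gather windows plus an antisymmetric
  difference make the self-force exactly zero and the scheme
  momentum-conserving.  CIC window deconvolution is available but off by
  default — combined with the central-difference gradient it overcorrects
  (12% vs 1.2% error against the Coulomb far field at 0.5 nm cells).
* **Integration.** Velocity Verlet, dt = 30 fs.  Density fields (and the
  electrostatic mesh) are recomputed every 20 steps and frozen in between
  (quasi-instantaneous field approximation).  Andersen thermostat at
  300 K: each step every particle's velocity is redrawn from the
  Maxwell-Boltzmann distribution with probability nu dt (nu = 7/ps,
  nu dt = 0.21).  All randomness flows from one integer seed;
  identical configuration + seed gives bit-identical trajectories.

## System construction

Surfactant counts follow the molarity exactly: N = round(c N_A L^3).  The
solvent fills the remaining volume at bulk bead density — water
33.33 molecules/nm^3 (4 per bead), cyclohexane 5.58 beads/nm^3 — after
subtracting a displaced volume of 0.89 nm^3 per surfactant.  The two fill
constants were fixed by requiring agreement within 1% with the reference
system compositions across 1–200 mM in both solvents.  Molecules are
placed by random sequential insertion (chains grown bond-by-bond) with a
0.25 nm minimum bead separation; velocities are Maxwell-Boltzmann with the
total momentum zeroed.

## Analysis pipeline

* **Clusters.** Two surfactant molecules are connected when any
  inter-molecular bead pair is within a cutoff (minimum image); aggregates
  are connected components.  The cutoff defaults to 0.8 nm — just past the
  ~0.75 nm first RDF maximum — and is exposed everywhere because cluster
  statistics are cutoff sensitive.  Bead-bead (not center-of-mass)
  connectivity is used so that tail–tail contacts, which hold the
  cyclohexane dimers together, count as contacts.
* **RDF.** Standard pair-count histogram against the ideal-gas shell
  expectation, frame averaged, with an optional per-molecule center-of-mass
  reduction.  Self pairs are excluded.
* **MSD / diffusion.** sigma^2(t) over multiple time origins (origins
  spaced by half the lag, a bias/variance compromise); Einstein fit
  sigma^2 = 6 D t + A over a window of 10–50% of the maximum lag by
  default.  The log-log slope alpha over the same window is reported as a
  linearity diagnostic (alpha ~ 1 diffusive, ~2 ballistic); trajectories
  read from wrapped formats are unwrapped by minimum-image displacement
  chaining.
* **CMC.** The free monomer fraction vs concentration curve is fitted by
  two least-squares lines over every ordered split with >= 2 points per
  side; the split minimizing the pooled squared residual wins and the CMC
  is the line intersection.  Near-parallel regimes (relative slope
  difference < 1e-9) are rejected as having no intersection.
* **SAXS.** I(Q) = 1 + 4 pi rho int (g(r)-1) r^2 sin(Qr)/(Qr) dr by
  trapezoid on the binned g(r) (default Q grid 0.1–5 nm^-1, 200 points);
  if |g(r_max)-1| > 0.05 a truncation warning is attached.  The
  Ornstein-Zernike line shape I0/(1+Q^2 xi^2) is fitted by nonlinear least
  squares with xi seeded from the half-maximum Q.
* **Packing parameter.** N_s = V_t/(A_c l_t) with the standard shape
  thresholds 1/3 (sphere/cylinder), 1/2 (cylinder/bilayer), 1
  (bilayer/inverted).

## Synthetic generators and what they do (not) show

Two generators make every analysis stage testable without the engine:
planted cluster configurations (compact molecular sublattices with known
partition, spread so inter-cluster gaps exceed twice any sensible cutoff)
and ideal Brownian walkers (Gaussian steps of variance 6 D dt).  They
validate the detectors — connectivity, histogram bookkeeping, Einstein
fits — under known ground truth.  They do not emulate correlated
hydrodynamics, polydisperse aggregate geometry, or field-mediated dynamics,
so passing them certifies the analysis machinery, not the realism of the
simulated physics; that is what the self-assembly runs are for.

## Problem sizes for the shipped studies

The packaged self-assembly studies use a reduced geometry: 10 nm boxes at
100 mM (about 60 surfactant molecules among ~8000 beads) run for 2e5
steps (6 ns), with statistics taken over the final half of the
trajectory.  That is large enough to develop the monomer-to-aggregate
crossover in water and the labile-cluster regime in cyclohexane, while the
full-scale protocol (28 nm boxes, 100 ns, six concentrations) is what the
CMC machinery is designed for; the two-regime fit itself is validated on
planted breakpoints.

## Known limitations

* hPF potentials are soft: contact values of g(r) are exaggerated and
  short-range structure is smoother than in pairwise models; peak
  positions, not peak heights, are the meaningful comparison.
* The reduced boxes put only a handful of molecules at millimolar
  concentrations, so monomer fractions at the lowest concentrations are
  strongly finite-size affected; the desk-scale CMC check is qualitative
  (aggregation at 50–100 mM, none at 1–2 mM).
* No barostat: all runs are NVT by construction.
* The mesh Poisson solver has no real-space short-range correction; below
  about two cell edges the effective interaction is smeared.  This matches
  the smooth-field philosophy of the model but means ion-pairing-scale
  electrostatics is qualitative.
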
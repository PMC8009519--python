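# hpfsurf

Coarse-grained simulation and analysis of a **polarity-inverted
surfactant**: a rigid hydrophobic adamantane head attached to a floppy
polar triethylene-glycol (TEG) tail ending in a hydroxyl group ("ADOH").
Conventional surfactants bury their hydrocarbon tails in water; this
molecule poses the mirror question — can it self-assemble into *inverted*
micelles in a nonpolar solvent like cyclohexane, with the polar tails
buried inside?  `hpfsurf` provides the machinery to answer that at desk
scale: a hybrid particle-field molecular dynamics (hPF-MD) engine and the
complete downstream analysis pipeline (cluster statistics, radial
distribution functions, diffusion from the Einstein relation, CMC
estimation, Ornstein-Zernike scattering fits, packing-parameter theory).

It is written for soft-matter/molecular-modelling researchers who want a
transparent, fully seeded, pure-Python (numba-accelerated) reference
implementation rather than a black-box MD package.

## The model in brief

ADOH is a five-bead chain A–E–E–E–T (A = adamantyl, E = TEG repeat, T =
OH); cyclohexane is one bead per molecule, one water bead is four
molecules.  Instead of pair potentials, species interact through their
smoothed number-density fields: the interaction energy

    W = ∫ dr/φ₀ [ ½ Σ_ij χ̃_ij φ_i(r) φ_j(r) + (1/2κ)(Σ_i φ_i(r) − φ₀)² ]

yields an external potential V_i = δW/δφ_i per species and forces
F = −∇V_i.  The χ̃ matrix (kJ/mol) carries the chemistry — notably
χ̃(A,W) = 33.75 (strong hydrophobic repulsion of the head from water) and
χ̃(A,C) = 0 (cyclohexane is a good solvent for the head).  Dynamics is
velocity-Verlet NVT (30 fs steps, Andersen thermostat at 300 K, field
update every 20 steps); cyclohexane systems optionally carry alternating
±0.4 e charges on the tail beads with ε_r = 5, solved by a spectral
Poisson mesh.  See `docs/methods.md` for every numerical choice.

## Worked example

```python
import hpfsurf as h
from hpfsurf.engine import SimConfig, run

ff = h.default_adoh_forcefield("W")                    # ADOH in water
state = h.build_system(h.SystemSpec(concentration=100, box_edge=10,
                                    solvent="W", seed=11), ff)
res = run(state, ff, SimConfig(n_steps=200_000, frame_stride=500, seed=12))
traj = res.trajectory

reports = [h.find_clusters(traj.frame(i), cutoff=0.8)
           for i in range(traj.n_frames)]
rdf = h.radial_distribution(traj, "molecule=ADOH and com",
                            "molecule=ADOH and com", r_max=4.5,
                            bin_width=0.05,
                            frames=slice(traj.n_frames // 2, None))
print(reports[0].monomer_fraction, reports[-1].monomer_fraction)
print(rdf.first_maximum())
```

prints (about 5 minutes on one core):

```
0.6333333333333333 0.36666666666666664
0.7250000000000001
```

i.e. over 6 ns the fraction of surfactant molecules that remain free
monomers drops from 0.63 to 0.37 as inverted-polarity micellar aggregates
nucleate, and the surfactant-surfactant center-of-mass pair correlation
develops its first maximum at 0.725 nm — the contact distance of two
molecules in an aggregate.  Running the identical protocol in cyclohexane
(`default_adoh_forcefield("C", charged_tails=True)`,
`electrostatics_on=True`) instead gives a monomer fraction that plateaus
near 0.5 and a monotone, exponentially decaying cluster-size
distribution (72% of clusters are monomers): labile clusters, no stable
micelles — the supercritical-mixture picture.

The same pipeline is packaged as narrative drivers:

```bash
python analysis/01_compositions.py            # system compositions table
python analysis/02_selfassembly_water.py      # micellization in water
python analysis/03_selfassembly_cyclohexane.py# the non-micellizing contrast
python analysis/04_cmc.py                     # CMC machinery + contrast
python analysis/05_diffusion_saxs_packing.py  # MSD, OZ-SAXS, packing
```

each writes its tables under `results/`.  A `hpfsurf` CLI exposes the
individual steps (`build`, `run`, `clusters`, `rdf`, `msd`, `cmc`,
`saxs`, `pack`); every output gets a JSON provenance manifest.

Packing-parameter theory from the molecular geometry (tail volume
0.603 nm³, head contact area 1.55 nm²) agrees:

```
>>> h.packing_parameter(0.603, 1.55, 1.0)
PackingResult(V_t=0.603, A_c=1.55, l_t=1.0, N_s=0.3890322580645161, shape='cylinder')
```

N_s between ~0.26 (full 1.5 nm contour length) and ~0.39 predicts
spherical-to-cylindrical aggregates — which is what the water runs form.

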
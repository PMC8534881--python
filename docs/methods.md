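# Methods

`atriafib` simulates how diffuse atrial fibrosis — fibroblasts,
myofibroblasts and fibrocytes intermingled with cardiomyocytes — changes
conduction, repolarization and electrogram frequency content in tissue under
persistent-AF electrical remodeling. This note records the models, the
numerical choices, and what the synthetic tissue does and does not stand in
for.

## Membrane models

**Cardiomyocyte.** The Courtemanche–Ramirez–Nattel (CRN) human atrial
model: 21 states (Vm, 15 Hodgkin–Huxley-type gates, 5 intracellular
concentrations), with the acetylcholine-activated inward rectifier
`I_KACh` added in the dose–response formulation of Kneller and co-workers.
Persistent-AF electrical remodeling is applied as multiplicative factors on
five maximal conductances, different per atrium:

| current | left atrium | right atrium |
|---|---|---|
| I_to  | ×0.25 | ×0.55 |
| I_Kur | ×0.55 | ×0.40 |
| I_Ks  | ×2.0  | ×2.5  |
| I_K1  | ×2.0  | ×2.0  |
| I_CaL | ×0.35 | ×0.35 |

The baseline transcription is validated by its published fixed point: the
unstimulated baseline cell settles at −81.19 mV and paces with APD90 ≈
289 ms at 1 Hz. Under remodeling the quiescent steady state moves to ≈
−84.8 mV, because doubling `I_K1` pulls Vm toward E_K; −81.2 mV remains the
*initial* (baseline) resting value. `find_resting_potential` integrates
until |dVm/dt| < 1e−6 mV/ms (default limit 20 s of model time) and reports
the drift when it does not converge.

**Fibrotic cells.** All three kinds share the MacCannell active-fibroblast
membrane (time-dependent K⁺ with two gates, inward-rectifier K⁺, Na⁺/K⁺
pump, background Na⁺; fixed intracellular milieu), resting near −49.6 mV.
They differ only in membrane capacitance and the tissue conductivity they
impose (cardiomyocyte 100 pF / 0.26 S/cm; fibroblast 6.3 pF / 0.078 S/cm;
myofibroblast 50.4 pF / 0.078 S/cm; fibrocyte 6.3 pF / 0.024 S/cm). The
fibrocyte is deliberately a fibroblast membrane with very low tissue
conductivity — no dedicated fibrocyte electrophysiology exists yet.

**[ACh] calibration.** The agonist concentration for `I_KACh` is not a
published number. It is fixed once at 7.5e−4 µM so that the no-fibrosis
LA-remodeled tissue sheet repolarizes with APD90 ≈ 118 ms, the working
point of the tissue experiments; it is a config parameter everywhere.

## Heterocellular coupling

A fibrotic node is a *heterocellular coupling*: the continuum node keeps its
cardiomyocyte membrane and a fibrotic-cell compartment hangs off it through
a gap-junction conductance (default Ggap = 3 nS, the canonical
myocyte–fibroblast coupling value; exposed in `SolverConfig`). The
alternative reading — the fibrotic membrane *replacing* the myocyte at the
node — is available as `coupling_mode="replace"`, but it is not the
default: with a quarter of the nodes inexcitable a 2D sheet blocks within
1–1.5 cm at high density, which contradicts the slow-but-sustained
conduction this class of models is built to reproduce.

## Tissue and fibrosis generation

Regular quadrilateral sheets at 300 µm spacing stand in for the atrial
mesh; regions are LA-like, RA-like or excluded-structure (never fibrotic).
Diffuse fibrosis relabels exactly round(density × n_eligible) uniformly
random eligible nodes (round half up, sampling without replacement,
seeded); multi-kind configurations split the nodes into equal groups, the
integer-division remainder going to kinds in canonical order so per-kind
counts do not depend on the seed. Any element with ≥1 fibrotic corner node
takes that kind's conductivity; with several kinds present the minimum wins
(conservative with respect to conduction slowing, and deterministic).

**Thin slabs.** High-density fibrosis puts a single 2D sheet below its
percolation limit, so the stochastic experiments use thin slabs: `nz`
(default 3) stacked sheets with independent fibrosis maps (per-layer seeds
derived from one SeedSequence), vertically coupled through the wall. Slabs
apply the element rule on *hexahedral* elements (8 corner nodes), the
volumetric reading of the rule — at 25% density this makes ≈ 90% of
elements fibrotic, which is what produces the order-of-magnitude conduction
slowing. Fiber orientation defaults to isotropic (angle 0); the anisotropy
of the real atria is inherited machinery that the desk-scale stand-in does
not reproduce.

## Monodomain solver

χ(Cm ∂V/∂t + I_ion) = ∇·(D∇V), with no-flux boundaries. Operator
splitting per 0.01 ms step: reaction first (Rush–Larsen exponential updates
for gates — voltage-dependent coefficients from lookup tables on a 0.02 mV
grid — forward Euler for Vm and concentrations), then an explicit diffusion
update. The diffusion operator is the assembled bilinear-quadrilateral FEM
stiffness (edge neighbors σ/6 per adjacent element, diagonal neighbors
σ/3) with a *consistent* mass matrix, applied exactly via two tridiagonal
solves per layer thanks to the tensor-product grid. The consistent mass
matters: with lumped mass the plane-wave CV at 300 µm carries ≈ 8%
dispersion error against a dx/2 reference; consistent mass brings it to
≈ 1.7%. Vertical (inter-layer) coupling is lumped.

The printed equation leaves the surface-to-volume ratio χ implicit; χ is
the unit-closing calibration constant, fixed once so the homogeneous sheet
(0.26 S/cm, dx = 300 µm, dt = 0.01 ms) conducts a plane wave at 62 cm/s:
χ = 1.762e5 cm⁻¹ at 1 µF/cm². It is recorded in every run manifest, and
`calibrate_surface_to_volume` reproduces the bisection. Node capacitances
enter the diffusion term as 100 pF / C_node in replace mode; in paired mode
every continuum node is a 100 pF myocyte.

Stability is checked, not assumed: per node, dt must not exceed the inverse
of the assembled coupling rate (×3 for the consistent-mass amplification of
the stiffest mode); the report names the binding node. Non-finite
potentials abort the run with node index and time.

**Stimuli** are rectangular 2 ms / 28 pA/pF pulses (depolarizing). An
"edge" site is a 3-node-deep boundary strip — a single node line cannot
reliably excite the sheet against its diffusive load. S1 plays the sinus
node along one edge; S2 is the 5-beat ectopic train at 110 ms cycle length
whose first beat sits at a coupling interval found by the descending
coarse-then-refined scan in `protocols` (activation = dV/dt crossing
10 mV/ms at sentinel nodes flanking the S2 site within 50 ms).

## Biomarkers

Activation time is the midpoint of the steepest-slope run of the first AP
exceeding −20 mV; APD90 runs from there to the interpolated crossing of
Vrest + 0.1 (Vpeak − Vrest), with Vrest the diastolic value immediately
before the upstroke (robust to slow drift); CV is the two-probe
straight-line estimate (default 10 nodes = 3 mm apart, mid-sheet) — under
zigzag conduction this is the *apparent* velocity, as in the two-node
measurement it mirrors. At high fibrosis density the apparent CV varies
substantially between fibrosis draws; the experiments therefore report
means over ≥5 seeds.

## Electrograms and dominant frequency

Unipolar EGMs are the element-wise discretization of the dipole-kernel
volume integral, −(σi/4πσe) Σ ∇Vm·∇′(1/‖r′−r‖) dv, with bilinear in-plane
gradients at element centers, dv = dx³, electrodes 0.2 mm above the (top)
surface, sampled at 1 ms; σi/σe defaults to 1 (pure amplitude factor).
Spectral pipeline: zero-phase 4th-order Butterworth band-pass 40–250 Hz,
rectification, zero-phase 20 Hz low-pass, then a Hann-tapered periodogram
zero-padded to a 0.1 Hz grid; DF is the highest peak in 2–20 Hz, ties
breaking toward the lower frequency. The left-to-right gradient is mean RA
DF minus mean LA DF. Morphology tags (single/double/fragmented) count
upward threshold excursions (0.2 of the robust amplitude) per activation
window, with fragmentation requiring cycle-length variation above 0.2.

## Desk-scale experiments and problem sizes

The reference experiments (also what `scripts/acceptance.py` runs) use
sizes chosen to resolve the measured quantity, not the full atrium:
a 70×7 strip for the no-fibrosis working point (APD90 118 ms, CV 62 cm/s);
60×28×3 slabs over 5 seeds for the 25% fibrocyte effect; a 100×16×3
two-region slab paced at 110 ms for ≥2 s for the DF gradient, with fibrosis
confined to the LA-like half, 6 electrodes per region, and up to four
seeded realizations screened for the 2:1 regime. The full
`pipeline.run_scenario` machinery defaults to a 100×100 split sheet and is
meant for CLI-driven studies.

## Known limitations

- The 2:1 LA conduction that creates the DF gradient is marginal by nature
  (diastolic interval ≈ 0 at the 110 ms cycle length); individual fibrosis
  draws can settle into 1:1 or 2:1, each stable once established. The DF-gradient
  experiment therefore (i) connects the regions through a narrow
  interatrial bundle (`carve_interatrial_isthmus`, 4 element rows),
  emulating the discrete interatrial connections of the real atria, which
  makes the junction's 2:1 response structural (its only other outcome is
  complete block), and (ii) screens up to three seeded realizations by
  their tissue-level LA/RA activation-rate ratio (upstroke counts at
  mid-LA columns — independent of the EGM/DF pipeline being evaluated),
  analyzing the first 2:1 realization and falling back to the closest one
  otherwise.
- With Ggap = 3 nS and one fibrotic cell per coupled node, high-density
  fibrocytes shorten tissue APD90 by ~13%, less than the ~20% of the
  reference experiments; stronger (or multiple) fibroblast coupling would
  close the gap but neither value is published, so the canonical coupling
  is kept.
- The AF-remodeled cell's emergent resting potential (≈ −84.8 mV) is more
  negative than the −81.2 mV quoted for the baseline model; the quote is an
  initial condition, not a steady state of the remodeled cell.
- Rotor and figure-of-eight narratives are observable from snapshots but
  not quantified (no phase-singularity tracking); anisotropy, realistic
  anatomy and patchy/compact fibrosis textures are out of scope.
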
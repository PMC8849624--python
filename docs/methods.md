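# Methods

`astrodensity` estimates how densely glial glutamate transporters (GLAST /
GLT-1, the EAAT1/EAAT2 homologs) populate the plasma membrane of mouse
hippocampal astrocytes, and what that density implies for glutamate uptake at
synapses.  The pipeline has five stages; each is summarised below together
with its assumptions, tunable parameters and known limitations.

## 1. Dot-blot quantification (`astrodensity.dotblot`)

**Model.** Dot intensities (raw integrated density, RID) respond sigmoidally
to the amount of protein spotted:

    F(x) = max / (1 + exp((xhalf - x) / rate))

Standard curves are built from serially diluted GST-tagged recombinant human
GLAST/GLT-1.  Because the recombinant protein differs from the native one in
size and purity, spotted standard masses are converted to **moles of
native-equivalent protein** before fitting:

    mol = mass x purity / MW_recombinant        (purity 92.82% / 86.93%,
                                                 MW 87,387 / 89,988 Da)

and sample readouts are interpolated on the mole axis and converted back with
the native molar mass (mouse 59,619 / 62,027 Da; rat 54,374 / 60,914 Da).
Fitting moles rather than nanograms makes one calibration serve both species;
the two conventions are interconvertible by a linear change of axis.

**Conversion chain.**  With the literature constants (97.8 mg protein per g
tissue, tissue density 1.05 g/cm3, astrocyte membrane density
3.15 um2 per um3 of tissue):

    mg/g  ->  uM = mg/g x 1.05 / MW x 1e6
          ->  molecules/um3 = uM x 602.214
          ->  molecules/um2 = (molecules/um3) / 3.15

Each step is exposed separately; an exact unit-chain inverse is tested.

**Numerical choices.** Unweighted least squares (`scipy.optimize.curve_fit`)
with init `max = 1.1 x max(RID)`, `xhalf = median mole amount`,
`rate = span/4`.  Background = mean of the PBS blank dots; negative corrected
RIDs are clipped to 0.  Technical dots (2-3) are averaged per condition, then
mean +/- SD is taken over n = 3 biological samples.  RIDs at or above the
fitted `max` raise an error (saturated dots cannot be inverted).

## 2. Morphology generation (`astrodensity.morphology`)

**Model.** A cell is a 5-um-radius spherical soma with 3-7 straight primary
branches (diameter 5 um) leaving radially at uniform random points.  Branches
are chains of cylindrical segments.  At each branching point the parent
spawns one daughter at opening angle `pi/6 + (level-1) pi/80` (azimuth
uniform about the parent axis, parallel-transported frame) and both emerging
diameters obey the biased Rall 3/2 rule `D^{3/2} = (f d2)^{3/2} + d2^{3/2}`
with `f ~ U(1, 1.5)`.  Segment lengths are `c + U(0, 10)` um with a per-cell
baseline `c0 ~ U(0, 25)` and per-primary `c ~ U(0, c0)`.  A branch terminates
(hemispheric tip) when an emerging diameter would fall below the per-primary
termination diameter `d_max ~ U(0.02, 0.15)` um, or when its branching-point
budget (15 for primaries, 11 for higher orders) or the 11-level cap is
reached; every branching point is followed by a thinner continuation
segment.  Leaves — 0.7-um cylinders with hemispheric caps, perpendicular to
the branch — are placed every `U(3, 8)` um of branch length, with diameters
from the 3/2 rule under the thickness-adaptive bias `f = 0.5 + 3 (1 + rho) D`
(`rho ~ U(0, 1)`); the terminal tip diameter is updated for the leaves the
terminal segment emits.

**Compartments.** soma = sphere area minus the spherical caps under the
primary branches; stems = lateral area of levels 1-2; tips/leaves = terminal
hemispheres + leaf surfaces; shafts = everything else.  The four areas sum to
the total surface area exactly.

**Morphometrics.** All areas/volumes are analytic cylinder/sphere sums.
Sholl intersections are counted on branch centrelines against 0.5-um-spaced
spheres (leaves excluded; tangency counted once).  The walking-cube cover
partitions space into 2-um cubes and keeps those intersected by non-core
structure (branches thinner than 1 um, at segment granularity, plus leaves);
the neuropil fraction is non-core volume over kept-cube volume and the
process density is the count of non-core segments plus leaves over kept-cube
volume.

**Design choices where the procedure was open.** Branch self-intersections
are permitted (no collision resolution); primary origins are not separated
by a minimum angle; leaf bases keep 0.35 um from segment endpoints so leaf
caps do not overlap branch-point geometry; branch diameter is constant along
a segment.

**Known limitation.** The stated sampling rules are internally inconsistent
with some of the reference morphometrics they were calibrated against: with
segment lengths `c + U(0,10)` (mean ~11 um) the generated trees are larger
(total branch length ~8e4 um, cell radius ~200 um) than the reference
ensemble (9.7e3 um, ~101 um), which evidently used an additional,
unreported, level-dependent length calibration.  This package implements the
stated rules; ensemble statistics that scale with absolute tree size
(tips/leaves surface fraction, cube-cover process density, S/V ratio)
therefore deviate from the reference values, and the acceptance checks for
those quantities report the deviation rather than masking it.  Structural
invariants (3/2 identities, budgets, compartment closure) are unaffected.

## 3. Trimer packing limits (`astrodensity.packing`)

A transporter trimer is a triangular prism (equilateral base, side
omega = 8 nm; height 6.5 nm) whose cytoplasmic protrusion `h_in` (0-3.5 nm,
conformation-dependent) sets an inner collision surface of radius
`r - h_in`.  Capacities per elementary shape:

* circle: `floor(pi / asin(omega / 2 r_-1))` chords;
* sphere: inner-sphere area divided by the equilateral *lunar* (spherical)
  triangle area `r^2 (3 acos((2r^2 - w^2)/(4r^2 - w^2)) - pi)` (Girard);
* cylinder: planar triangular rows of height `omega sqrt(3)/2` wrapped on the
  inner circumference, two triangles per circumferential chord cell;
* soma: sphere capacity scaled by the area left after removing the spherical
  caps under the K primary branches;
* tips: half the sphere capacity (hemispheres); leaves: cylinder + cap.

The membrane area one trimer occupies is the curved patch above a centred
flat triangle, computed by adaptive quadrature of the surface-area element
(authoritative) with a re-derived closed form as cross-check; the two agree
to better than 0.1% everywhere tested, and both reduce to
`sqrt(3) omega^2 / 4` in the flat limit.  Branch-point crowding removes a
disc of the daughter's diameter from the parent's available area (the same
treatment as the soma caps); leaf insertion discs are *not* excluded.
Whole-cell results report trimer density `sigma = n/A`, monomer density
`3 sigma`, and occupied fraction `Phi = S/A` per compartment.  At `h_in = 0`
on strongly curved shapes the patch-area sum can exceed the available area
by ~2-3% (the patch is measured on the outer surface, the budget on the
inner); occupied area is capped at the compartment area so `Phi <= 1`.

## 4. Compartment distribution (`astrodensity.compartments`)

Literature soma-normalised expression ratios (tips/leaves : shafts : stems :
soma) — GLAST 0.6 : 0.5 : 0.8 : 1, GLT-1 2.3 : 1.4 : 0.7 : 1 — are scaled so
that the area-weighted mean over compartments returns the measured
whole-cell density: `d_i = mean x r_i / sum_j a_j r_j`.  Combined ratios for
both transporters are abundance-weighted sums renormalised to soma = 1
(homogeneous of degree 0); with early-age abundances this reproduces the
published combined vector ~1.4 : 0.9 : 0.7 : 1 to one decimal.  Relative
density `d_i / sigma_model,i` and effective occupied fraction
`phi_exp = d/sigma_model x phi_model` compare measured densities against the
packing maxima; consistent with the published arithmetic, `sigma_model`
here is the *trimer* capacity density (the monomer density is three times
larger and is also reported).

## 5. Reaction-diffusion simulation (`astrodensity.cleftsim`)

**Geometry.** A 3-um reflective cube holds seven synapses (central + hexagon
at 1 um centre-to-centre): 250-nm-radius hemisphere pairs separated by a
20-nm cleft.  Four synapses (central + three alternating neighbours, 4/7 =
57%) carry a glial sheet: a 50-nm-thick, 250-nm-tall cylindrical-shell
section covering 43% of the perimeter, 20 nm off the synapse edge.  2,000
glutamate molecules are released at t = 0 from the cleft centre (or the
cleft edge nearest/farthest from the sheet).

**Dynamics.** Per 1-us step, free glutamate takes Gaussian displacements
with `D* = 3.30e-6 cm2/s` inside any cleft and `1.29e-6 cm2/s` outside
(tortuosity lambda = 1.6), with specular reflection at every surface
(small-penetration mirror; a move that cannot be resolved is rejected).
Transporters populate both sheet faces at surface density `sigma_astro`
(count = round(area x density)), diffuse laterally at 0.23e-8 cm2/s confined
to their face, and follow the 3-state scheme To -> ToG -> TiG -> To with
rates 18e6 M-1 s-1, 3,594 s-1 (unbind), 6e3 s-1 (translocate), 150 s-1
(reset); the rate constants are taken as already temperature-adjusted.
Unimolecular transitions use per-step probabilities `1 - exp(-k dt)`
(guarded < 0.1).

**Bimolecular binding rule.** A free molecule within a 5-nm shell of an
outward-facing transporter binds with probability
`p = k_on dt / (N_A V_shell)` (half-sphere shell for wall-mounted
transporters).  Because the diffusion step (16-26 nm) is large compared to
the shell, successive steps decorrelate and the rule reproduces mass action;
this is verified against the closed-form 3-state ODE in a well-mixed box
(20-repetition envelope) rather than assumed.  Translocated glutamate moves
to an absorbed pool; unbound glutamate re-enters 6 nm off the face.  Free +
bound + translocated is conserved exactly.

**Readouts.** Concentrations every 10 us in the PSD cylinder (r = 125 nm,
h = 20 nm), the perisynaptic annulus (125-250 nm) and the remaining
extracellular volume (half-open assignment: by |z|, then radius).  Receptor
open probabilities are integrated deterministically from the waveform,
`dP/dt = Q([glu](t)) P` (LSODA, simplex preserved to 1e-8), with schemes
supplied as JSON rate matrices.  The published AMPA/NMDA rate constants are
not reproduced here; the bundled 5-state AMPA-like and NMDA-like schemes are
synthetic generic parameter sets, so only *relative* open-probability trends
across densities and release sites are meaningful.

**Boundary choice.** The original environment treated the world box as
transparent; here the default is reflective so that particle bookkeeping
closes (an `open` boundary is available and marks leavers as escaped).
Peak-concentration readouts occur within the first few ms, long before the
boundary matters at 3 um.

**Problem sizes.** Full scale is 2,000 molecules x 100,000 steps (100 ms);
the test suite exercises the same kernels at 400-2,500 steps and 1-20
repetitions, which covers every peak-based readout (cleft peaks occur within
~1 ms) while keeping the suite fast.  The density sweep uses
sigma_astro in {0, 10, 100, 1,000, 10,000, 20,000} um-2.

## 6. Synthetic data (`astrodensity.synthetic`)

Dot-blot tables are generated through the same forward model the analysis
inverts: a known sigmoid on the mole axis, standards at 7 masses x 2-3
technical dots, 3 biological sample dots, PBS blanks, and multiplicative
log-normal noise on RID (imaging/exposure variability; default CV 5%).  The
default spotted membrane protein (5 ug) keeps even the most abundant target
(GLT-1 at 4.5% of total protein) inside the calibration curve's dynamic
range.  What passing recovery tests show: the fitting/inversion chain is
unbiased under the assumed noise model.  What they do not show: robustness
to real-blot pathologies (saturated exposures, spatial background gradients,
antibody non-linearity), none of which are modelled.

Morphology fixtures (soma-only cell, single-primary cell) and
transporter-free scenes provide fast deterministic inputs for the consuming
stages.

## Reproducibility

Every stochastic component takes a seed (`numpy.random.Generator`); a seed
fixes the whole astrocyte, simulation repetition, or synthetic table.
`scripts/acceptance.py --seed N --out results/acceptance.json` regenerates
the headline numbers from scratch: the three conversion-chain surface
densities, the apposed-ECS percentage, and the 10-cell morphology ensemble
statistics (seeded from N via `SeedSequence.spawn`).
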
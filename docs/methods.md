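# Methods

`angioscaffold` simulates how blood vessels invade a porous biomaterial
scaffold implanted against host tissue, over a six-week horizon. Three
coupled components drive the simulation: a voxelized scaffold geometry, a
one-dimensional growth-factor transport model, and a lattice agent-based
model (ABM) of endothelial-cell behaviour. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Coordinate conventions

The scaffold is a 3D voxel grid `grid[ix, iy, iz]` of cubic voxels with
labels MATERIAL, PORE and DISTAL_LAYER. The y axis is the invasion axis:
the host vasculature sits against the face at y = 0, the growth-factor
source (a degradable layer of loaded microspheres, the "distal layer")
against the opposite face at y = H. Voxel centres are at
`(index + 0.5) * spacing`; a vessel that occupies voxel `iy` is credited
with reaching depth `(iy + 1) * spacing` (the far edge of the voxel), so a
vessel in the top voxel layer scores a normalized invasion of exactly 1.

## Scaffold generators

**Sphere-templated scaffolds.** Equal spherical pores of diameter d
(default 115 um, the bead-template size scale) are packed so that
overlapping pairs sit at centre distance `c = d * sqrt(1 - NPC^2)`, which
makes the circular opening (throat) between them exactly `NPC * d` wide.
NPC — normalized pore connectivity, mean throat diameter over mean pore
diameter — is therefore the controlled quantity. Placement is randomized
candidate sampling: an existing pore is displaced by c in a random
direction; a candidate that would overlap a second pore at an off-target
distance is snapped onto the circle at distance c from both, so every
throat in the packing has the target NPC. Placement stops after 500
consecutive rejected candidates (no admissible location remains). Pores
may cut through the host face, which is what produces a finite interface
porosity and gives host vessels access to the pore space; the lateral
walls and the distal face remain sealed, matching an implant held in a
shell with only its bottom face open to tissue.

**Salt-leached scaffolds.** Rectangular pores with edge lengths drawn
uniformly from 300-500 um (the sieved salt-crystal range) are rotated about
their centres by independent multiples of 10 degrees on all three axes,
voxelized, and accreted at uniform random positions until the bulk porosity
first crosses the target (default 64.4%, the measured porosity of the
experimental hydrogels). A candidate that is more than 50% redundant with
existing pore space is rejected; otherwise neighbouring pores may overlap
freely — at 64% fill large overlaps are geometrically unavoidable, and
pore-to-pore interconnectivity is deliberately uncontrolled in this
scaffold type.

**Morphometrics.** Bulk porosity is the pore-voxel fraction of the usable
domain; interface porosity the pore fraction of the host-face layer (one
pore diameter thick by default). Pores are identified from generation
records when present (each pore voxel assigned to its nearest recorded
centre — for equal overlapping spheres this is the bisector plane through
the throat), otherwise by watershed segmentation of the Euclidean distance
transform. Throats are measured on the voxel grid: cross-section planes
perpendicular to the centre axis of each face-adjacent pore pair are swept
through their overlap region at sub-voxel resolution, and the throat is the
equivalent-circle diameter of the minimal cross-section area. Against the
closed form for two intersecting spheres, `2 * sqrt(r^2 - (d/2)^2)`, this
estimator is accurate to about half a voxel even for thin, near-tangent
throats; the watershed fallback (whose pore envelopes are only estimated)
is accurate to roughly 10%.

## Growth-factor release and transport

PDGF-BB transport is one-dimensional Fickian diffusion along y,

    dC/dt = D_eff * d2C/dy2,   C(0, t) = 0,   C(H, t) = C_b(t),

with the surrounding tissue an infinite sink at the host face and the
distal layer imposing a time-varying Dirichlet concentration. The factor is
assumed not to bind or react with the scaffold, so there are no reaction
terms; D_eff (default 50 um^2/s, a typical effective diffusivity for a
~25 kDa growth factor in a hydrogel) lumps steric hindrance and any weak
matrix affinity, and `fit_deff` recovers it by least squares from an
observed concentration (or transport) series when measurements exist.

The experimental release-kinetics series behind the boundary condition is
not distributed here. `synth_release_curve` provides a parametric stand-in:
cumulative release `M(t) = dose * (b + (1-b) * (1 - exp(-k t)))` — an
initial burst fraction b (default 0.15) plus first-order release (default
k = 0.014/h, i.e. ~90% released within about a week, a typical PLGA
microsphere time scale and the value that reproduces the reported ~week-4
regression onset; see Calibration). Any measured time-vs-cumulative-mass
CSV can be substituted. The distal-layer boundary concentration follows
from a well-mixed compartment balance: released mass enters the layer
(volume = scaffold cross-section x 0.5 mm thickness) and drains into the
scaffold with the quasi-steady rate `k_out = D_eff / (H * h_layer)`;
the balance is integrated exactly (piecewise-constant release rate with an
exponential integrator).

"X% slower release" (Cases B-F: 20, 50, 200, 300, 500% slower) stretches
the cumulative-release curve's time axis by `1 + X/100` and recomputes the
boundary concentration from the compartment balance; total released mass is
unchanged by construction, which is the dose-conserving correction
(stretching a concentration profile directly instead multiplies it by the
reciprocal of the stretch factor, and `rescale_release` does exactly that
when given a solved field).

The solver is a finite-volume discretization (default 80 cells over 4 mm)
with backward Euler time stepping (default dt = 600 s, unconditionally
stable; an explicit scheme with a CFL guard is kept for cross-checks).
Face fluxes are accumulated with the same implicit values the scheme uses,
so the discrete balance released-in = stored + drained-to-sink closes to
machine precision; the solution matches the semi-infinite erfc solution to
well under 1% at early times.

## The endothelial-cell rule base

One tick is 6 h. Each tick applies, in order: field time advance,
activation, tip migration (with stalk-elongation bookkeeping), anastomosis,
regression. All randomness comes from a single seeded generator, so a
(config, seed) pair reproduces a trajectory bit for bit.

* **Activation.** Source endothelial cells are seeded on pore voxels of the
  host face (default 40 per mm^2 of face). A quiescent source whose sensed
  concentration reaches the activation threshold (1 ng/mL, the reported
  order of magnitude for endothelial activation) becomes a migrating tip
  and starts a sprout. Because the host face itself is held at zero by the
  sink, sensing happens at a filopodia-scale depth ahead (100 um).
* **Migration.** A tip moves through the 26-neighbourhood of pore voxels
  (material is impassable), to the neighbour with the strictly highest
  concentration; ties (all upward neighbours, since the field depends on
  depth only) break randomly. When no improving pore neighbour exists —
  the way up is walled off — the tip searches a new route: with probability
  `explore_prob` (default 1.0) it steps to a random pore neighbour at equal
  or higher concentration (any neighbour if none qualifies), else it
  stalls. Migration is gated by the same look-ahead sensing as activation:
  a tip whose environment has dropped below the activation threshold stops
  migrating. The step budget is 40 um per tick (160 um/day unobstructed),
  executed as single-voxel substeps so narrow throats are navigated
  honestly.
* **Elongation / proliferation.** The trailing stalk grows by the tip's
  displacement; cell bookkeeping partitions each vessel's length into cells
  of at most 50 um (a new stalk cell is inserted whenever the trailing cell
  would exceed its maximum), so no cell ever exceeds the maximum length and
  total vessel length equals the sum of cell lengths.
* **Anastomosis.** Two elongating tips of different capillaries within the
  fusion distance (25 um) fuse; a tip also fuses with any cell of a
  preformed capillary chain (a prevascular segment is fusion-competent
  along its length). All proximity pairs in a tick are merged first
  (converging groups become one component), then the fused tips stop
  elongating. The two fusing vessels become anastomosed and **stable** —
  assumed to carry blood flow; pressure gradients are not modelled — and
  every preformed chain in the merged component becomes stable with them
  (a passive conduit is perfused as soon as it is connected). Growing
  branch sprouts elsewhere in a component stay non-stable until they close
  a loop of their own.
* **Re-sprouting.** A source whose sprout has fully regressed sprouts
  again; a source whose sprout has fused sprouts a branch from the distal
  end of its stabilized component (where the concentration is highest).
  The branch shares the component's identity — it cannot re-fuse its own
  network — so successive branches thread past it and extend the stable
  front. This branching ratchet is what lets a preformed network become
  perfused region by region.
* **Regression.** Cells need the growth factor to survive: a non-stable
  vessel whose distal cells sit below the regression threshold (1 ng/mL)
  retracts from its distal free end inward, at most 24 um per tick per
  free end (a preformed chain has two; regression is capillary shortening,
  not instantaneous deletion, and never disconnects a surviving vessel
  from its origin).  The retraction rate is slower than migration, so a
  partially regressed front persists for a week or two after growth-factor
  withdrawal before settling onto the stable network.
  Stable vessels are immune — once flow is assumed, survival no longer
  depends on the growth factor. A fully pruned vessel dies and frees its
  source.

Growth-factor consumption by cells is not modelled; the field declines only
because microsphere release is exhausted.

## Prevascularization

Preformed capillary chains are laid into the pore space before the run:
chain starts are uniform over the pore voxels of the chosen region (whole
scaffold, top half, or bottom half along y; half regions get half the
seeds so density matches; default 90 seeds for the full region), and each
chain extends by uniform random adjacent-pore steps, stopping when ten
consecutive draws find no admissible pore location — chain lengths
therefore vary with the local pore structure (a hard cap of 100 voxels
bounds them). Chains enter the simulation as
ordinary non-stable, non-migrating vessels: they regress like any vessel if
unsupported, and chains that physically touch (within one voxel) are
pre-linked into one component, so a single host fusion perfuses the whole
touching cluster.

## Evaluation metrics

The scaffold is cut into three equal vertical slabs along x (perpendicular
to the invasion axis; the slab axis is configurable). Normalized vessel
invasion is the deepest vessel reach from the host face divided by scaffold
height, averaged over the three slabs (an empty slab contributes zero).
Normalized anastomosed invasion restricts to vessels that are anastomosed
and stable. Total capillary length sums every living cell's length
contribution. Replicates are summarized as mean +- sample SD (n-1); a
single replicate reports SD 0 with a flag.

## Packaged studies, problem sizes and calibration

Four studies are packaged (`angioscaffold.experiments`), each defaulting to
five replicates with independently seeded scaffolds and simulations:

| study | scaffold | domain (x,y,z mm) | voxel | GF |
|---|---|---|---|---|
| interconnectivity | spherical, NPC 0.25 vs 0.45 | 1.0 x 1.6 x 1.0 | 12.5 um | 600 ng, Case A |
| gf_dose | salt-leached, 64.4% | 1.4 x 4.0 x 1.4 | 20 um | 2 / 20 / 200 ng |
| release_rate | salt-leached, 64.4% | 1.4 x 4.0 x 1.4 | 20 um | 200 ng, Cases A-F |
| prevascularization | spherical, NPC 0.45 | 1.0 x 1.6 x 1.0 | 12.5 um | 600 ng, Case A |

The salt-leached studies keep the experimentally stated 4 mm height and
shrink only the x-z cross-section (invasion is measured as a normalized
depth along y, so the cross-section mainly sets replicate noise). The
sphere-templated implants are bead-templated hydrogel slabs whose height is
not stated; the package models them as 1.6 mm thick. Their growth-factor
condition is likewise unstated ("high GF" loading); the packaged default of
600 ng with the synthetic release curve makes the concentration history in
the thin implant cross the survival threshold at depth around week 4, the
regression onset that study reports. The printed 200 ng dose is used for
the salt-leached gradient studies, where it is stated.

Agent parameters (migration speed, stalk length, fusion distance, source
density, exploration) are published only in earlier work and are re-derived
here by calibration: the exposed defaults above were tuned so that the
replicate-mean invasion curves reproduce the reference simulation values
(week-3/6 high-NPC invasion 0.83/0.57; ~50% vs ~30% stable vascularization
at week 4 for high vs low NPC; week-3/6 gradient-study invasion 0.72/0.47;
over 50% anastomosed by week 2 and ~80% invasion by week 6 with full
prevascularization). They are deliberately configuration, not constants.

## Known limitations

* The synthetic burst + first-order release curve is a stand-in for the
  measured kinetics. Two consequences: at low doses (2-20 ng) the boundary
  concentration barely crosses the 1 ng/mL activation threshold, so those
  runs show near-zero invasion rather than the modest transient invasion
  seen experimentally; and among the slowed-release cases, Case D (200%
  slower) shows no regression within the 6-week window — its onset falls
  after week 5, as reported, but a single-exponential release cannot also
  place it before week 6 while keeping Cases E/F regression-free (for the
  family `T(c) = c*(T_A - ln(c)/k)` the required orderings are mutually
  inconsistent). A measured release series restores both behaviours
  without code changes.
* Blood flow and pressure are not modelled: "stable" is a binary flag set
  by anastomosis, and stable vessels are frozen rather than remodelling.
* Tissue formation, pericytes, immune cells and matrix remodelling are out
  of scope; comparisons with tissue-invasion measurements assume tissue
  depth tracks vessel depth.
* The lattice ABM inherits voxel anisotropy (26-neighbour moves) and the
  invasion metric is an extreme statistic (deepest reach per slab), which
  makes single replicates noisy; conclusions should rest on replicate
  means, as the packaged studies report them.
* Synthetic scaffolds emulate geometry (pore size, throat width, porosity)
  but not material degradation, swelling, or fibrin filling; passing tests
  show the rule system reproduces the reference in-silico behaviour, not
  that it predicts any particular in-vivo series.
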
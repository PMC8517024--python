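# Methods

## The cell model

`cellmech` simulates a two-dimensional coarse-grained cell built from three
bead-spring structures:

* a **membrane ring** of 201 type-0 beads on a circle of diameter 5.25 µm;
* a **nuclear ring** of 33 type-1 beads, diameter 1.5 µm;
* **radial actin filaments** in the annulus between them, of two kinds:
  type I (10 beads, 1.5 µm, innermost bead bonded to the nearest nuclear
  ring bead) and type II (8 beads, 1.2 µm, free at both ends).  Filaments
  occupy equally spaced angular slots in the repeating pattern I, II, II
  (11 type I + 22 type II = 33 filaments by default, one per nuclear bead).
  The outermost bead of every filament — the *head*, the bead nearest the
  membrane — carries label 3.

Four potentials define the mechanics.  Bonded beads interact through a FENE
spring, `U(r) = -kF·Δr²max/2 · ln[1-((r-r0)/Δrmax)²]`, and consecutive bead
triples through a bend term `U(θ) = kB/2 (cos θ - cos θ0)²`.  Non-bonded
pairs follow a Lennard-Jones potential written with its minimum at the
equilibrium distance, `U(r) = ε[(σ/r)¹² - 2(σ/r)⁶]`, for the two tunable
attractions of the model, and its purely repulsive WCA truncation for all
other pairs.  The two attractions are the model's biology:

* **ε₀₀** — membrane-membrane attraction, the stand-in for cell-cell
  adhesion (it acts across cells in a colony);
* **ε₀₃** — filament-head-to-membrane attraction, the stand-in for
  actomyosin contractility (it couples the cortex to the membrane).

### Units and default parameters

All dynamics are dimensionless.  One reduced length unit equals the
membrane bead spacing (σ of the (0,0) pair rule), i.e.
`length_unit = π·5.25 µm/201 ≈ 82 nm`; the µm dimensions above are stored
as metadata.  Bead mass is 1; energies are in units of the repulsive ε.

| parameter | default | rationale |
|---|---|---|
| kF00 (membrane FENE) | 40 | stiff, nearly inextensible membrane |
| kF11 | = kF00 | filament/nuclear bonds share the membrane stiffness |
| kF13 | = 5·kF11 | stiff head anchor class (used when `anchor_heads=True`) |
| Δrmax | 0.5·r0 | standard FENE window, prevents bond crossing |
| r0, θ0 | as built | the constructed cell is mechanically relaxed |
| kB | 5 | soft bending: rings and filaments are semiflexible |
| σ00, σ03 | 1.0 | membrane bead diameter defines the length unit |
| σ11, σ13, σ33 | 2.0 | fat filament beads: a crowded, load-bearing interior |
| σ01 | 1.5 | mixing rule between membrane and filament diameters |
| LJ cutoff | 2.5 σ, energy-shifted | standard practice |
| baseline ε₀₃ | 0.8 | mid-flank of the contraction response (see below) |
| baseline ε₀₀ | 1.0 | comparable to the repulsive energy scale |

The cos²-form bend potential is quartically soft around θ0 = π, so
filaments have negligible small-deflection bending rigidity at any
reasonable kB; mechanical resistance of the interior instead comes from
excluded volume.  That is why the filament beads carry a larger diameter
(σ = 2): the 33 filaments then form a crowded granular scaffold, anchored
to the nucleus through the type I inner bonds, rather than a set of
independently buckling threads.

### How contractility stiffens the cell

With increasing ε₀₃ the membrane binds to the filament heads and drags the
free type II filaments inward; the cortex contracts until the filament
crowd jams against the nucleus (the equilibrated membrane radius falls
from ≈ 32 to ≈ 26 reduced units over ε₀₃ = 0.4 → 1.6).  An indenting probe
then has to compress a pre-contracted, adhesively coupled scaffold instead
of deflecting a loose membrane, which raises the measured force.  The
response saturates above ε₀₃ ≈ 1.5 once the cortex is fully jammed, so the
default sweep levels {0.5, 1, 2}×0.8 = {0.4, 0.8, 1.6} straddle the rising
flank.  Varying ε₀₀ in a single cell only modulates the weak
second-neighbour attraction within one membrane, so its force response is
nearly flat — the model's central contrast.

## Time integration

Velocity Verlet with BAOAB-style Langevin splitting.  With damping = 0 and
temperature = 0 the O-step vanishes and the scheme is plain symplectic
velocity Verlet (used in the NVE conservation gate: relative drift of the
total energy < 10⁻³ over 10⁴ steps at dt = 10⁻³).  Production runs use
dt = 0.005, damping γ = 0.1 and temperature T = 0.002:

* γ = 0.1 keeps the dynamics overdamped enough to relax but small enough
  that the viscous drag of the deforming membrane (≈ γ·v·N_moving) stays
  well below the elastic forces being measured — with γ = 1 the
  indentation force is dominated by drag and insensitive to the model's
  elasticity;
* T = 0.002 provides seed-to-seed variability and a realistic noise floor
  without burying the ε₀₃ contrast (bead-scale thermal forces ≈ √(2γT)).

Neighbour lists come from a KD-tree with a 0.4 σ skin, rebuilt when any
bead has moved half the skin.  FENE overextension or non-finite positions
raise a typed error naming the step (and truncate an indentation curve
with a rupture flag).

## Virtual AFM protocol

The tip is one type-7 bead of interaction radius σ07 = tip radius + 0.5,
coupled to a moving anchor by springs kx = ky = 50 and interacting with
all cell beads through WCA (it can only push).  The tip bead is damped
(γ_tip = 1) but excluded from the thermostat: it is a macroscopic
apparatus, not a Brownian particle.  Protocol:

1. the cell equilibrates alone for 20 000 steps (contraction converges in
   ≈ 15 000 at γ = 0.1), with a membrane arc of 35 % of the ring on the
   far side tethered to the substrate (k = 20) — without this the cell
   would translate rather than deform;
2. the tip is placed `start_gap = 2` outside the *equilibrated* membrane
   surface along the approach axis (placement before equilibration would
   alias the ε₀₃-dependent contraction into the contact point);
3. the anchor approaches at V = 0.05 with a soft start (linear velocity
   ramp over the first 0.5 of travel), for `max_travel = 12` with the
   default cell-scale probe (radius 12, chosen to average over several
   filament spacings; sharper tips show stick-slip between scaffold
   contacts);
4. the reported force is the anchor-spring deformation projected on the
   approach direction, averaged within each recording window, minus the
   instantaneous apparatus drag γ_tip·v(t) — so the pre-contact baseline
   is zero up to thermal noise.

The probe operates at a fixed finite rate, as experimental AFM does: the
adhesive cortex rearranges plastically during indentation, so the absolute
response is rate-dependent and all contractility/adhesion comparisons are
made at matched V.  The apparatus itself is quasi-static — against a rigid
(fully pinned) target, doubling the anchor springs leaves the
force-vs-tip-position relation unchanged once the spring compliance
travel − F/k is removed (verified in the test suite).

Contact is the first of two consecutive samples exceeding 1 % of the peak
force.  The sweep readout ("force at reference travel") averages the curve
over a post-contact band centred at 65 % of the post-contact range with
half-width 25 % — the deep part of the curve where the jammed-scaffold
response discriminates contractility levels; the shallow part mostly
reflects bare membrane bending, which is ε₀₃-independent.  The stiffness
proxy is the least-squares slope over the middle 60 % of the post-contact
range.

## Colony cohesion pull assay

Colonies are hexagonally packed copies of one cell (gap 1.0 < LJ cutoff so
the inter-cell (0,0) adhesion engages); a cell is classified *center* with
six lattice neighbours, else *edge*.  For the pull assay the colony first
equilibrates for 15 000 steps — long enough for the ε₀₃-driven contraction
to settle — with every non-target cell's nuclear ring softly tethered to
the substrate (k = 5); then the outward-facing 25 % membrane arc of the
target cell is tethered to anchors ramped outward at 0.05 length/time
through a total spring stiffness of 20 (slow enough that the recorded
force reflects detachment, not anchor lag — at 4x this rate the readout is
rate-dominated and insensitive to the model parameters).  The pull-out
force is the maximum projected spring force before the target centroid has
moved one cell diameter; runs that never detach within a 2-diameter anchor
budget are flagged censored.  Pair rules are type-based and global, so at
cell-cell junctions the filament heads of one cell also attract the
neighbouring cell's membrane through ε₀₃ — the junctional face of
contractility, as adherens junctions couple cortical actin across cells.
Together with contraction pre-tensioning the contacts this raises the
pull-out force with ε₀₃ by roughly 8 % across the default level range — a
modest but consistent cohesion-strengthening effect.  With both ε₀₀ and
ε₀₃ at zero the extraction force collapses to drag-scale noise.

Colony work uses a reduced-size cell (60 membrane / 12 nuclear beads, 12
filaments, same cell and nucleus µm diameters, filaments shortened to
1.0/0.8 µm to preserve excluded-volume clearances at the coarse
resolution — `GeometryConfig.compact()`), keeping a 7-cell assay within
interactive runtimes while preserving the mechanics.

## Hertz–Sneddon elastography

Experimental-style force-indentation curves are fitted to
`F = C·E/(1-ν²)·tan(α)·δ²` with δ = travel − contact point, jointly
estimating E and the contact point by bounded least squares; C = 2/π for a
conical (Sneddon) indenter (default) and C = 0.7453 for a pyramidal one.
Defaults α = 9°, ν = 0.45.  With travel in µm and force in nN the modulus
comes out in kPa.  Moduli above 20 kPa can be filtered
(`filter_moduli`) to remove substrate-dominated indentations.  Parameter
recovery is the module's gate: noiseless synthetic curves recover E to
< 1 %, and the median error under 2 % multiplicative noise is < 5 % over
50 replicates.

## Image and profile quantification

* **Circularity** 4π·area/perimeter²; the perimeter is the length of the
  smoothed sub-pixel marching-squares contour (moving average, window 7),
  accurate to ≪ 1 % for smooth shapes at ≥ 50 px — naive pixel-edge
  counting cannot reach the circularity-1 anchor for a digitized disc, and
  the 4-direction Crofton formula (available as the alternative estimator)
  is biased up to ~7 % for elongated axis-aligned shapes.
* **Solidity** area / convex-hull area via the rasterized hull.
* **Neighbour distances**: each cell contributes its 5 nearest-neighbour
  distances; the pooled set is binned as a unit-area density (a Gaussian
  KDE is available).
* **Ruffles**: local maxima of an AFM height profile with topographic
  prominence strictly greater than 15 nm; the paper-style amplitude has no
  defined baseline, so prominence is used.  Per-cell counts sum the
  (conventionally four) profiles.
* **Focal adhesions**: rolling-ball background subtraction (r = 30 px) on
  the paxillin channel, Tsai moment-preserving auto-threshold (reimplemented
  on a 256-bin histogram), hole filling; mean auto-threshold on actin,
  dilate → fill holes → open with a 3×3 square, one iteration; the FA mask
  is the AND of both; FAs per cell divides the component count by the
  nucleus count of the supplied label mask.
* **FRET**: ratiometric index `R = (FRET - α·donor - β·acceptor)/donor`
  averaged per masked region, excluding non-positive-donor pixels with a
  warning; single-chain index = per-FA mean of FRET/CFP.
* **Nuclear vs cytoplasmic** classification calls N=C when the two means
  differ by at most 10 % of the larger (the equality band is otherwise
  undefined); the tolerance is exposed.

## What the synthetic data does and does not emulate

Generators plant known ground truth (modulus, shape indices, FA counts,
FRET index maps, peak prominences, point-pattern statistics) and serialize
it next to the data, so every analyzer is tested by forward-model
inversion.  They emulate geometry, bleed-through mixing, and simple
Gaussian/multiplicative noise — not optics (no PSF, no photon statistics),
not segmentation errors (nucleus masks are exact), and not biological
heterogeneity.  Passing round-trips therefore validates the estimators'
correctness, not their robustness to real microscope artefacts.

## Known limitations

* The model is two-dimensional and its forces are in reduced units; only
  orderings and ratios are claimed, never kPa values.
* The contractility-stiffness link runs through cortex contraction and
  interior crowding; membrane-localized prestress without contraction is
  not represented.
* The cos²-form bend potential leaves filaments quartically soft around
  straight configurations; filament persistence length is effectively set
  by excluded volume, not kB.
* The vinculin-sensor FA masking variant (CLAHE + LoG) is intentionally
  not implemented: its published description names operations without
  parameters.
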
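# cellmech

Coarse-grained cell mechanics in 2D, with the quantification toolkit that
surrounds such experiments.  The package is built for studying how
**actomyosin contractility** and **cell-cell adhesion** shape the
mechanical response of stem-cell-like cells and colonies, using a
bead-spring model probed by a virtual AFM tip, plus the image-analysis
measurements (shape indices, focal-adhesion morphometrics, FRET indices,
membrane-ruffle counts) used to characterize the corresponding wet-lab
phenotypes.

## The model

A cell is a closed membrane ring (201 beads, diameter 5.25 µm), a nuclear
ring (33 beads, 1.5 µm) and 33 radial actin filaments — type I (10 beads,
1.5 µm, anchored to the nucleus) interspersed 1:2 with type II (8 beads,
1.2 µm, free).  Beads interact through:

* FENE bonds  U(r) = −κF·Δr²max/2 · ln[1 − ((r−r0)/Δrmax)²]
* bend triples  U(θ) = κB/2 (cos θ − cos θ0)²
* Lennard-Jones pairs  U(r) = ε[(σ/r)¹² − 2(σ/r)⁶] for the two tunable
  attractions — membrane–membrane **ε00** (adhesion) and
  filament-head–membrane **ε03** (contractility)
* WCA (repulsive-only LJ) excluded volume for everything else.

A virtual AFM tip — a probe bead anchored to a moving apparatus through
two orthogonal springs (kx, ky) — indents the cell at constant approach
velocity; the recorded force–distance curve yields a stiffness readout.
Raising ε03 contracts and jams the cortex and stiffens this response;
raising ε00 does not, which is the model's central, experimentally
motivated contrast.  Experimental-style curves are fitted with the
Hertz–Sneddon contact model F = C·E/(1−ν²)·tan(α)·δ² (α = 9°, ν = 0.45 by
default) to recover an elastic modulus in kPa.

## Worked example

```python
import numpy as np
from cellmech.model_builder import build_cell
from cellmech.md_engine import SimulationConfig
from cellmech.virtual_afm import run_indentation, stiffness_proxy, fit_hertz
from cellmech.synthetic_data import make_sneddon_curve

# indent a single cell at low and high contractility
for eps03 in (0.4, 1.6):
    beads, table = build_cell(eps03=eps03)
    curve = run_indentation(beads, table,
                            sim=SimulationConfig(damping=0.1,
                                                 temperature=0.002, seed=1,
                                                 record_every=400))
    c = curve.contact_travel()
    deep = curve.force[curve.travel > c + 4].mean()
    print(f"eps03={eps03}: contact at {c:.2f}, deep-indentation force {deep:.3f}")

# fit a synthetic experimental curve (travel in um, force in nN -> E in kPa)
curve, truth = make_sneddon_curve(E=2.2, noise=("multiplicative", 0.02), seed=0)
fit = fit_hertz(curve, half_angle=9.0, poisson=0.45)
print(f"fitted E = {fit.modulus:.2f} kPa (planted {truth['E']} kPa)")
```

Output:

```
eps03=0.4: contact at 2.20, deep-indentation force 0.284
eps03=1.6: contact at 3.70, deep-indentation force 0.438
fitted E = 2.19 kPa (planted 2.2 kPa)
```

The deep-indentation force (reduced units) rises by half across the
contractility range while the contact point shifts with the contracted
cell surface; the Hertz fit recovers the planted modulus to about a
percent under 2 % noise.

A command-line interface mirrors the library:
`cellmech indent`, `fitmodulus`, `sweep`, `pull`, `shape`, `nndist`,
`fa-seg`, `fret`, `ruffles`, `make-fixture` (see `cellmech --help`).

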
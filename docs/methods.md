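# Model and methods

`callusim` simulates bone regeneration in a segmental long-bone defect
as a hybrid continuum–discrete system on a 2D quarter-callus domain.
This note records the model equations, the reasoning behind every
parameter that matters, the numerical scheme, and what the simulator
does and does not capture.

## Geometry

One fourth of the fracture callus is modelled (two-fold symmetry): x
runs along the bone axis from the gap midline (x = 0, a symmetry plane)
to the retained cortical bone end, y radially outward.  The domain width
is half the gap size plus a 1 mm cortical-end segment; the height is
1.5 mm (0.5 mm endosteal/marrow band, 0.25 mm cortex, 0.75 mm
periosteal band — murine tibia scale; all config constants in
`GeometryParams`).  The cortex is inert geometry: no field lives in it
and no flux crosses its faces.  The *central callus area* — the zone of
reduced biological potential — is the part of the callus further than a
periosteal-collar width (0.5 mm, halved for very small gaps) from the
bony end.

## Fields and units

Ten fields evolve on the grid, integrated in model units (cells scaled
by 1e6 cells/ml, matrix by 0.1 g/ml, growth factors by 100 ng/ml,
oxygen in %); every scenario interface is dimensional.  Motile cells
(MSCs `c_m`, fibroblasts `c_f`) diffuse (0.01 mm²/day) and chemotax
weakly up the osteochondrogenic-factor gradient; chondrocytes,
osteoblasts and the three matrix densities do not move; growth factors
diffuse at 0.3 mm²/day; oxygen at 2e-12 m²/s (0.17 mm²/day, an
effective tissue value).

## Reaction network

* Proliferation is logistic in total cell density and inhibited by
  total matrix density; each cell type carries an oxygen-response
  curve (MSC peak 4 %, chondrocyte peak 3 %, fibroblasts and
  osteoblasts near-normoxic).
* MSC differentiation: to osteoblasts at high oxygen (half-saturating
  in `g_bc` at 100 ng/ml), to chondrocytes at moderate oxygen with a
  cooperative Hill-2 dependence on `g_bc` (half-point 200 ng/ml).  The
  cooperativity makes chondrogenic commitment a switch: baseline
  central concentrations (10 ng/ml) commit essentially nothing, while a
  1 µg/ml injection commits the whole pool within a day.  Chondrogenic
  conversion consumes `g_bc` stoichiometrically (50 GF units per cell
  unit), so a fixed dose can only commit a limited pool — the reason a
  combined cell+GF injection commits only part of the injected cells.
* Endochondral ossification: chondrocytes convert to osteoblasts where
  oxygen returns; osteoblasts resorb cartilage and deposit bone; bone
  and cartilage production saturate as total matrix density approaches
  the physiological maximum.
* Growth factors: osteoblasts (strongly) and chondrocytes (weakly)
  produce `g_bc`; `g_v` (VEGF) is produced by hypoxic *viable* cells —
  production is zero above 3 % O2, zero below the producing cell's own
  survival tension (moribund cells do not synthesise VEGF), and
  saturates in producer density (half-max at 5e4 cells/ml).  The
  saturation means a dense injected bolus gains no more vascular
  guidance than the endogenous hypoxic front.
* Death: sharp switches just below each survival tension — osteoblasts
  below 0.7 %, MSCs below 0.5 %, chondrocytes below 0.3 % (chondrocytes
  are the most hypoxia-tolerant skeletal cells; cartilage is
  physiologically avascular), fibroblasts only below 0.1 %.  Surviving
  fibroblasts fill the dead centre with dense fibrous matrix; this
  occlusion is what arrests late recolonisation of the centre and
  matches the fibrous-tissue-filled centre seen in failed defects.

## Oxygen

Consumption is Michaelis-Menten, `Q_i c_i n/(K_m + n)` with
`K_m = 0.5 %` and maxima ordered chondrocytes < MSCs < osteoblasts <
fibroblasts (defaults 0.15, 3.5, 4.0, 4.7 × 1e-13 mol/cell/day).  With
these magnitudes a proliferating MSC pool is self-limiting: the
standard compromised centre collapses below the survival tension within
about a week, driven by its own expansion.  Active vessels deliver
`G_n = 3.2e-12 mol/(EC·day)` per endothelial agent, spread over the
grid-cell tissue volume (Henry solubility 1e-8 mol·ml⁻¹·%⁻¹, slab
thickness 0.3 mm) and capped as tissue oxygen approaches the vessel
tension (8 %).

## Vasculature and Dll4-Notch

Endothelial agents form polyline branches (stalk spacing 0.05 mm).
Tips migrate at 0.07 mm/day where local `g_v` exceeds 0.2 model units,
along the `g_v` gradient blended with a persistent heading and a
von-Mises deflection (κ = 20); persistence lets tips cross plateaus of
uniform guidance ballistically.  Branching requires `g_v` above 0.4,
clearance from existing junctions (0.12 mm) and a tip-fate decision
from the Dll4-Notch chain dynamics: VEGF drives Dll4, a cell's Dll4
activates Notch in its chain neighbours and suppresses their Dll4;
synchronous relaxation to the fixed point yields salt-and-pepper
tip/stalk patterns with no adjacent tips.  Exactly symmetric chains are
broken by a seeded 1e-6 Dll4 jitter.  Tips fuse with a foreign branch
within 0.08 mm once they are at least 1 mm long (young sprouts are not
fusion-competent; this prevents instant self-annihilation of the
plexus).  Segments connected to an initial seed are active and deliver
oxygen; a stricter loop-closure rule is available in config.

## Scenarios

The standard compromised condition starts the central area with
2e3 cells/ml MSCs, 10 ng/ml `g_bc`, 1e4 cells/ml fibroblasts,
0.01 g/ml fibrous matrix and 3.7 % O2 (tenfold-reduced cells/GF
relative to the tissue near the bony ends); MSCs/fibroblasts are
released from the periosteum and marrow near the bony ends and `g_bc`
from the degrading bone ends during the first 14 days (the soft-callus
release window; the muscle-environment sources below are explicitly
90-day boundary conditions, which is what distinguishes them).  Host
cases: A (muscle-derived vessel seeds along the whole gap border),
B (outer half only; fraction is a config constant), C (2 µg/ml `g_bc`
Dirichlet on the muscle border, 90 days), D (2e4 cells/ml MSC
Dirichlet, 90 days), E–J their combinations.  Treatments set
concentrations over the central area (replace-if-higher, capped at
carrying capacity): cells 2e5/ml (permissive study) or 1e6/ml
(timing study), growth factor 1 µg/ml.

## Numerics

Explicit operator splitting per step (dt = 0.02 day on the default
0.25 mm "desk" grid): flux-form transport (5-point diffusion,
first-order upwind taxis — positivity over accuracy at fronts),
explicit reactions with a positivity limiter (a sink can at most empty
a cell in one step), then oxygen delivery/consumption, Dirichlet
releases, and an agent tick every 0.25 day.  Flux-form differencing
makes no-flux runs conservative to round-off; negative excursions are
clipped with a logged mass diagnostic and a hard failure above 1e-6 of
the field total.  A backward-Euler sparse diffusion solve is
config-gated (`semi_implicit_diffusion`) for the high-resolution
"paper" profile (dx = 0.025 mm); all shipped tests and the acceptance
script use the desk profile, whose 90-day run takes seconds.

## What the tests show — and what they do not

The test battery checks conservation, equivalence with a naive dense
stepper, the closed-form 1D oxygen profile, lateral-inhibition
patterns, bit-exact determinism, and the qualitative biology on the
coarse grid: bone fraction non-increasing with gap size with the
critical size at 3 mm; the standard 5 mm defect ending as a stalled,
capped, centrally-hypoxic non-union near 50 % bone; full muscle
vascularisation (A) and sustained muscle MSC supply (D) rescuing the
defect while partial vascularisation alone (B) fails; and a day-zero
1 µg/ml growth-factor injection healing the partially vascularised
defect.  These are desk-grid, single-seed outcomes of a calibrated
model; they demonstrate internal consistency of the mechanism, not
quantitative prediction for real fractures.

Known limitations, held deliberately and tested as expected failures:

* A day-zero **cell** injection into the partially vascularised defect
  bridges in this implementation (it should not improve healing
  appreciably): the injected pool survives beside the muscle-derived
  plexus and seeds an endochondral template.  Every global change that
  killed this route also destroyed the growth-factor rescue.
* In the fully compromised environment, early cell injections
  over-perform rather than under-perform no treatment for the same
  reason; delayed injections correctly out-perform no treatment, with
  effectiveness rising after vascular recovery.
* Case C (sustained muscle GF release) over-performs (bridges here).

Also out of scope by design: mechanics and interfragmentary strain,
vasculogenesis, inflammation, bone remodelling, callus shape change,
and any scaffold material.
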
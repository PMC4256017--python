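# Methods

## Model

`ductsim` simulates a 2D cross-section (or longitudinal section) of a
mammary duct as a cellular Potts model. The lattice holds one integer agent
index per pixel (0 = culture medium) inside an immutable one-pixel medium
frame; 1 px = 1 µm. Dynamics are Metropolis pixel-copy attempts: per MCS,
one attempt per lattice site picks a random interior pixel and a random one
of its 8 neighbors, and proposes overwriting the pixel with the neighbor's
index. The proposal is accepted with probability min(1, exp(−ΔH/T_m)).

The effective energy has four terms. Contact adhesion sums J(τ₁, τ₂) over
2nd-order (8-neighbor) pixel pairs of unlike index; J is negative between
live cells (contact is favorable), zero for any pair involving medium or
necrotic debris. The volume term λ_V (V − V_t)² and surface term
λ_S (S − S_t)² constrain each agent's pixel count and boundary-face count.
The spring term λ_ij (l_ij − L_ij)² acts on center-of-mass links between
neighboring cells.

A cell annihilated by pixel copies (V → 0) keeps paying λ_V V_t², which
makes spontaneous cell loss prohibitively expensive — only the event layer
(apoptosis) retires agents, zeroing their targets.

### Surface metric

An agent's surface S is its count of 4-neighbor faces adjoining a different
index. This taxicab metric overestimates Euclidean length by the
Cauchy–Crofton factor 4/π: a digital disk of diameter 10 has ≈ 40 boundary
faces against a true circumference of 31.4. Target surfaces are therefore
specified as Euclidean circumferences and converted by 4/π on assignment
(S_t = 31.4 → 40 face units), so a round cell at target volume sits at its
surface optimum. Without this conversion the face-unit target is
unattainable for *any* shape and acts as a permanent inward tension that
leaves cells ~4 px under target volume and stalls duct filling.

### Spring links (contractility)

Links are focal-adhesion-like: they form on contact and persist. Each agent
carries two junction classes — up to two *lateral* links to same-layer
neighbors (the polarity chain along each monolayer) and up to two
*cross-layer* links tethering the LEP layer to the myoepithelium. At
initialization each agent's two nearest eligible partners are linked when
the nomination is mutual; during a run a link dissolves only when its
partners drift beyond 25 px (2.5 cell diameters), and agents with a free
slot re-link to the nearest eligible agent within 15 px (centers of
touching cells), closest pairs first. Springs are elastic in both
directions: with target lengths (8 px LEP–LEP and LEP–MEP, 5 px MEP–MEP)
below the 10 px resting spacing they contract the tissue, while a
compressed chain pushes back and keeps a monolayer from collapsing into a
ball.

Two modeling choices here matter and were fixed by their consequences for
tissue integrity. (i) Links must persist rather than be re-derived from
scratch each step: a freshly re-optimized nearest-neighbor chain forms a
compressed elastic ring along the lumen surface that artificially props the
lumen open. (ii) Cross-layer tethers must exist: with lateral links only,
the heterotypic spring constants are inert, and differential adhesion
(γ_LEP,medium = 10 > γ_MEP,medium = 2.5 in interface-tension terms) peels
the LEP monolayer off the myoepithelial wall within ~1500 MCS in tubular
geometries.

## Event layer

All event rules run once per MCS, after the Metropolis sweep.

**Mitosis.** Every `mitosis_interval` MCS, ⌈0.25 × #LEP⌉ live LEP are
drawn without replacement and each is bisected by a straight cut through
its center of mass. The cut's orientation is set relative to the local
layer normal — the radial direction from the duct's medial axis (the disk
center for the circular duct; the skeleton segment(s) for cylinder and
bifurcation): *perpendicular* divisions keep both daughters in the layer,
*parallel* divisions place the daughter on the luminal side, *random* picks
a uniform angle. Daughters inherit the parent's type and full-size targets
and regrow through the volume constraint; there is no explicit growth
phase, so the cadence is the model's only proliferative timescale. Cells
below 2 px skip division with a logged warning. The standard cadence
pairs (15 events ↔ 65 MCS, 20 ↔ 50, 25 ↔ 38, 30 ↔ 32 per 1000 MCS) are
built in; other counts use ⌊0.96 × run / n⌋, keeping the final event
shortly before the evaluation point. With preferential end proliferation
enabled, cells in an end region carry twice the sampling weight
(weighted-key sampling), reproducing the ~2× division frequency at
engineered-tissue ends.

**Apoptosis.** An LEP with ≥ 10 *other live LEP* centers within 25 px (2.5
cell diameters) is overcrowded; each overcrowded LEP is removed with the
configured probability (0–1%) per MCS, its pixels reverting to medium
immediately. Only the luminal epithelial population is counted:
crowding-induced extrusion is an epithelial-sheet phenomenon, and counting
the enclosing myoepithelium would mark the intact bilayer itself as
overcrowded once the contractile springs tighten the ring (spacing ~8.5 px
puts the mixed count at 11), eroding the normal duct. With LEP-only counts
the quiescent ring sits at 4–6 neighbors and apoptosis acts specifically
on luminal accumulation. An optional flag exempts luminally placed
daughters of parallel divisions from apoptosis (the protected-progeny
variant); it is off by default — enabling it with inheritance makes growth
unbounded, because every cell of the expanding mass is protected.

**Necrosis.** An LEP whose center of mass lies ≥ 100 px (≈ the oxygen
diffusion limit; the rule is purely geometric, no nutrient field) from the
nearest MEP *pixel* becomes necrotic: its type changes, its adhesion and
spring couplings drop to zero, and its pixels remain as debris. The
boundary is inclusive at exactly 100 px. Distance uses a Euclidean
distance transform of the MEP mask; a center-of-mass prescreen skips the
transform while no LEP is within 15 px of triggering.

## Geometries

All three archetypes share one recipe: a skeleton (a point; a segment; a
Y of three segments) defines a distance field; pixels under the lumen
radius are medium, the next 10 px band is the LEP monolayer, the band
beyond that the MEP monolayer. Each band is partitioned into ~10 px cells
by Voronoi assignment to seeds spaced evenly along the band centerline,
which guarantees a watertight bilayer; cells round up within ~10 MCS under
the constraints. The circular duct fixes 50 LEP (lumen radius 75 px,
lattice 240²); the cylinder is a stadium (lumen half-width 25 px, straight
length 300 px); the bifurcation is a trunk (150 px) splitting into two
150 px branches at 45°. Tubular geometries label all pixels whose skeleton
projection lies within one lumen diameter (50 px) of a skeleton tip as
*end* region, the rest of the tissue as *duct* region. A 10×10 px square
ring cannot tile a circle without overlap, so the circle's initial LEP area
is ~5020 px rather than exactly 5000.

## Morphology classification

Pure functions of a snapshot. Enclosed lumena are 4-connected medium
components not reachable from the exterior, at least half a cell (50 px) in
area. The cascade:

1. **comedo** — necrotic debris present and the duct filled (retained
   lumen area < one cell area, 78.5 px);
2. **solid** — filled without necrosis;
3. **cribriform** — ≥ 2 lumena and a *spanning bridge*: an 8-connected
   component of luminal (non-wall) LEP anchored to ≥ 2 wall cells whose
   center-to-center chord passes within half a lumen radius of the duct's
   medial axis ("cells extending completely across the duct"). Components
   containing the monolayer itself are excluded — the intact ring would
   otherwise satisfy any chord test. Central necrosis under a cribriform
   verdict sets an evidence flag rather than re-labeling;
4. **micropapillary** — ≥ 1 live LEP with no MEP contact inside the
   periphery (extra luminal cells) while the lumen is patent;
5. **normal** otherwise.

Invasion: a live LEP counts as invading when it has moved out into the
surroundings, which requires all three of (i) center of mass beyond the
initial tissue outline dilated by one cell diameter (growth alone does not
trip the test immediately), (ii) beyond the *current* myoepithelial
envelope — the MEP mask morphologically closed (12 px, sealing sub-cell
gaps), hole-filled, and dilated one cell diameter — so an expanding but
intact duct keeps its boundary cells inside, and (iii) membership in a
cell component detached (8-connectivity) from the main tissue mass, so
cells that poke through a myoepithelial gap while remaining part of the
cohesive tissue are not scored. Invaders are attributed to the end or
duct region by the skeleton-projection rule. Gaps in the MEP layer
without invading cells count as breaches, never invasion. Replicate
consensus uses the 80% modal rule, else "mixed".

## Reproducibility and numerics

Each run derives two generators from its seed: an explicit-state
xorshift64* stream (splitmix64-seeded) drives the compiled Metropolis loop,
and a numpy Generator drives event-layer choices; identical parameters give
bitwise-identical trajectories. The incremental ΔH used by the kernel is
validated against a from-scratch energy recomputation to < 1e-9 in the test
suite. Ties in the division cut (pixels exactly on the cleavage line) go
to the parent; a degenerate cut falls back to a median split.

T_m defaults to 20 — the default contact energies span 5–20 in magnitude,
and this keeps membranes fluctuating without melting cells; it is exposed
in the configuration.

## What the batch experiments do and do not show

The experiment harness reruns the study protocols at configurable
replicate counts; the test suite uses scaled-down counts (1–10 replicates
per condition, with shortened tubular blueprints where noted in the test
fixtures) chosen so the full suite runs on one
core in tens of minutes, while `scripts/acceptance.py` uses 50 replicates
per condition. The generator is the model itself — there is no separate
synthetic-data layer — so passing tests demonstrate internal
reproducibility of the model's regimes, not fidelity to any particular
patient histology.

Known limitations: no basement membrane (so "invasion" means passing the
tissue outline, not membrane degradation), no ECM/stroma, no nutrient
diffusion (necrosis is a distance rule), 2D only, no cell-cycle or lineage
biology beyond parent→daughter indices. Under the default parameters the
zero-apoptosis, 10-event schedule leaves a small (~1 cell-area-scale)
residual lumen at 1000 MCS where the reference phenomenology is complete
filling: closing the last medium pocket requires cells to exceed their
target volume, and at 2nd-order contact energies the adhesion gain does not
cover that cost; the duct classifies as late micropapillary rather than
solid at that checkpoint and fills shortly after.
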
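# Methods

`morphosim` couples a particle-based mechanical model of an epithelial
monolayer to a morphogen reaction–diffusion network solved on a dynamic
triangular mesh, and uses the morphogen signal to drive cell division.  The
target system is a *Drosophila*-wing-disc-like tissue: a Dpp (BMP-homolog)
source stripe along the anterior–posterior (AP) midline, an exponential
gradient across the AP axis, and growth controlled by the temporal rule
that a cell divides when its sensed signal has risen by 50% since the start
of its cycle.

## Mechanical submodel

Cells are subcellular-element objects: `N^I` internal nodes represent the
cytoplasm and `N^M` membrane nodes (a closed cycle) represent the plasma
membrane plus cortex.  Node motion is overdamped,

    eta dx_i/dt = -grad_i E_total,

integrated with explicit Euler (default `dt_mech = 0.02`, damping
`eta = 1`).  Five pairwise interaction classes compose `E_total`:

| class | pair | form | default |
|---|---|---|---|
| II  | internal–internal, same cell | Morse, truncated at the well | U0=0.35, r_eq=0.60, xi=0.25 |
| MI  | internal–membrane, same cell | Morse, truncated at the well | U0=0.30, r_eq=0.70, xi=0.30 |
| MMS | consecutive membrane nodes | linear spring | k=10, l0=0.20 |
| MMD | membrane–membrane, different cells | Morse, truncated at the well | U0=0.50, r_eq=0.15, xi=0.08 |
| Adh | membrane–membrane, different cells | full Morse | U0=0.08, r_eq=0.18, xi=0.15 |

The Morse well is `U(r) = U0 [exp(-2(r-r_eq)/xi) - 2 exp(-(r-r_eq)/xi)]`.
II and MI are truncated at the minimum and shifted (purely repulsive):
they encode cytoplasmic and membrane pressure.  An earlier design with the
full attractive Morse tail on II/MI let the cytoplasm condense into a
dense cluster under the long-range many-body attraction, collapsing the
cell; cutting the tail and balancing pressure against ring tension (l0
below the natural membrane-node spacing) yields a robustly round cell: a
single relaxed cell reaches an isoperimetric ratio `4 pi A / P^2 ≈ 0.98`.
Lengths are in µm with a relaxed cell radius near 1.1; all values are this
package's own calibration (no published parameter table is reproduced) and
sit in `MechParams`.

An explicit-Euler displacement guard (`max_displacement = 0.25` µm/step)
raises on instability.  During fixture relaxation and growth, where a
freshly inserted node can transiently overlap an existing one, the step is
instead rescaled *globally* so the largest displacement equals the guard.
The global rescale (rather than per-node clamping) keeps the net
displacement of the tissue exactly zero; per-node clamping was observed to
make the whole tissue drift slowly, which matters because the morphogen
source is anchored to the AP midline fixed at the initial tissue centroid.

### Growth, cycle and division

Growth adds internal nodes by a Poisson process with rate
`g * N^I_birth` per unit time, anchored to the internal count at cycle
start: node count grows linearly and the doubling time is exactly `1/g`
(with the reference `g0,max = 1.1e-4`, the shortest cycle is 9090 time
units).  Interphase growth stops at twice the birth count
(`growth_cap_factor = 2`): a fully grown cell waits for the division
trigger.  Daughter growth rates decay generationally,
`g <- 0.9 g` per division (a time-based exponential decay is selectable).

A flagged cell enters a mitotic phase for `mitotic_duration` time units
during which its cortical stiffness (MMS) is multiplied by 3 and its
membrane pressure (MI) by 1.5 — a mitotic-rounding proxy.  The split plane
passes through the cell centroid perpendicular to the long axis (largest
second-moment eigenvector) with a 5° seeded angular jitter (Hertwig-type
rule).  Internal nodes partition by side; each daughter membrane is the
parent membrane arc on its side closed by the division chord (offset half
an MMD equilibrium distance so the daughters do not overlap), resampled
evenly in arc length to the parent's membrane node count and rescaled
about its centroid to preserve the clipped-polygon area.  Divisions with
fewer than two internal nodes, or that would leave a daughter empty, are
refused.  Membrane node count per cell is constant between divisions;
membranes are re-sampled only at division.

## Dynamic mesh

The chemistry mesh is rebuilt from membrane geometry at every coupling
step:

1. cells are neighbors when their minimum membrane–membrane node distance
   is below `neighbor_threshold` (default 0.45 µm ≈ 2× the equilibrium
   membrane gap of two adhered cells, measured once on a two-cell
   fixture);
2. close membrane-node pairs of two neighbors (within
   `pairing_factor * neighbor_threshold`, pairing factor 1.5 to bridge
   sparse interfaces) produce midpoints forming the *common edge*;
3. common-edge endpoints cluster into *junction vertices* by single-linkage
   within the neighbor threshold, plus a topology-driven rule: for every
   mutually adjacent cell triple, the endpoint of each pair interface
   nearest the triple corner joins that corner's junction regardless of
   distance (purely metric clustering left occasional sliver gaps at loose
   three-cell corners);
4. each cell is fan-triangulated from its center (membrane centroid) to
   its perimeter vertices, so two neighbors share the junction–junction
   edge exactly and the mesh is watertight (Euler characteristic 1 on a
   disc-like tissue, counting only interior faces);
5. membrane arcs on the tissue boundary get `Round[theta/(pi/3)]`
   (minimum 1) evenly spaced membrane nodes as boundary vertices — one
   vertex per 60° of arc keeps boundary fan triangles near equilateral;
6. shared edges shorter than `l_intersect` (default 0.2 µm) collapse to
   their midpoint, converting the three triangles around a short edge into
   two well-shaped ones; residual slivers below 5° minimum angle that the
   short-edge merge cannot reach are discarded (the crack left behind has
   near-zero area).

Per adjacent triangle pair the mesh stores the contact edge length
`A_{i,n}` and the centroid distance `l_{i,n}` used by the finite-volume
flux.  Triangles are tagged *boundary* per cell: every triangle of a cell
with uncovered membrane carries the flag, matching the picture of
absorbance by the peripheral (hinge) zone acting on boundary cells.

## Chemical submodel

Simplified mode evolves a single morphogen,

    d[Dpp]/dt = D lap[Dpp] + v / (1 + (x/(r_s L))^n_s) - d [Dpp],

with `x` the unsigned distance from the AP midline and `L(t)` the current
tissue half-width (maximum `|x|` over triangle centroids).  Full mode adds
the receptor Tkv, the Dpp–Tkv complex and pMad: reversible binding
(k_on, k_off), Hill activation of pMad by the complex, and negative
feedback of pMad on Tkv synthesis between `v_min` and `v_max` with
half-saturation `k_P`.  Only Dpp diffuses.

Diffusion is finite-volume on the triangle mesh:
`dc_i = dt/V_i * D * sum_n A_in (c_n - c_i)/l_in` (the default dialect; a
literal dialect without the `1/V_i` normalization is selectable, as is a
source-modulated Dpp degradation carrying the same Hill factor as
production — the default for full mode — versus uniform degradation, the
default for simplified mode).  Time stepping is explicit Euler at 0.7× the
stability bound `min_i V_i / (D sum_n A/l)`; since the quasi-steady state
is a fixed point of the iteration, the converged field does not depend on
the step size.  Quasi-steady convergence requires
`|c(t+dt) - c(t)| / (c(t) dt) < 1e-4` for every triangle and species;
triangles whose concentration is below `max(1e-12, 1e-8 * max c)` use the
absolute difference (the floor scales with the field so float-rounding
noise next to absorbing boundaries cannot stall convergence).  Two
robustness floors protect the explicit step on imperfect meshes: triangle
areas are lumped up to 5% of the median and centroid distances to 25% of
the median; both are inactive on well-shaped meshes, where mass
conservation under no-flux is exact to accumulation error.

Boundary conditions: `absorbing` pins Dpp to zero on boundary triangles at
every step (peripheral degradation by the hinge region); `no_flux` needs
no action because the finite-volume scheme has zero flux across boundary
edges.

On a strip of equilateral triangles (centroid connectors perpendicular to
shared edges, making the two-point flux consistent) the solver reproduces
the closed-form decay length `lambda = sqrt(D/d)` of the
production–diffusion–degradation balance within a few percent when the
domain exceeds ~5 lambda and the source Hill is sharp (n_s = 8 in the
validation runs; with a shallow source tail the fitted decay length is
biased up because production leaks into the fit region).

## Coupling

Every `exchange_interval` (default 200) mechanical time units: remesh;
initialize each triangle with its cell's previous average (daughters
inherit the parent value); run chemistry to quasi-steady state; average
per cell (area-weighted).  With `g0,max = 1.1e-4` and the 200-unit
interval this is 45 chemical updates per shortest cycle and an exchange
frequency of 0.005.  The division rule compares the cell's current signal
to the memory stored at its cycle start (first chemical update after birth
or t = 0): divide when `(c - c_mem)/c_mem >= 0.5` (inclusive).  Simplified
mode reads Dpp; full mode reads pMad by default (both selectable).  A
memory of zero never triggers.  Flagged cells complete the mitotic phase
before splitting; daughters appear with fresh (unset) memories.

## Synthetic data

`make_initial_tissue` builds the canonical starting condition: hexagonally
packed near-circular patches (default 100 cells, 16 membrane + 8 internal
nodes each, unit radius), pre-relaxed mechanically.  It emulates the
packing statistics of a wing-disc pouch — after relaxation the
neighbor-count mode is 6 — but none of the biological heterogeneity:
no cell-size variability beyond packing noise, no pre-existing morphogen
field, no apical-basal structure.  Tests passing on these tissues
demonstrate the numerics and the coupling logic, not quantitative
agreement with any real disc.

## Desk-scale trend experiments

The reference conditions (100 cells, 9090-unit cycles, horizons of many
cycles) are far beyond a desktop budget, so directional claims are probed
at fixed scaled conditions (`morphosim.experiments`): 20 cells with 14
membrane + 6 internal nodes, `g0 = 5e-3` (shortest cycle 200 units),
exchange interval 25 (8 updates per cycle), horizon 400 units (two
shortest cycles), five seeds with majority voting.  These runs compare
directions — absorbing vs no-flux boundary, low vs high degradation,
strong vs weak receptor feedback — not absolute cell numbers.  Under
no-flux the mean morphogen concentration is pinned near `v r_s / d` (the
source stripe is a constant area fraction of the tissue), the 50% rule is
rarely met, and growth stalls after the first size doubling; under
absorbance the interior concentration keeps rising as the boundary sink
recedes (L/lambda grows), sustaining division.

Two full-network choices in these experiments deserve note.  First, the
pMad production Hill is used in its *activating* form so pMad is a
monotone readout of Dpp signaling (the repressive form — production
maximal at zero complex — remains the package default and is what the
chemistry oracle checks; with a repressive readout the division rule and
the observed signal profiles are mutually inconsistent), with `v_P = 4`
so the feedback on Tkv is fully engaged at low `k_P` (receptor production
near its minimum across the tissue).  Second, the division rule in full
mode reads **Dpp** rather than pMad: the negative feedback loop actively
buffers pMad against the slow rise the temporal rule listens for (pMad up
-> Tkv down -> complex down -> pMad down), so a pMad-based rule stalls
precisely when the feedback is strong; reading Dpp lets the feedback act
through the morphogen spread it controls — lower `k_P` lowers receptor
levels, widens the Dpp gradient (measured pMad decay length 1.33 vs 0.43
at `k_P` 0.1 vs 10 on the 20-cell fixture), and sustains division across
a larger share of the tissue.  Both signals remain selectable in
`CouplingConfig.rule_signal`.

Desk-scale limits of the shape readout: tissue circularity (bounding-box
height/width) distinguishes degradation regimes only when divisions are
confined to a thin midline stripe of a much larger tissue
(`lambda << L`, hundreds of cells).  At 20–40 cells the source region
spans a sizable fraction of the tissue, added cell mass redistributes
isotropically, and arms that barely divide remain trivially round, so the
circularity comparison is dominated by packing noise (observed spread
±0.1 against contrasts of similar size).  The cell-count and
angular-flatness comparisons are the discriminating readouts at this
scale; the angular comparison is defined only over seeds in which both
arms produced division events.

## Known limitations

- The mesh generator assumes a single connected, disc-like tissue;
  fragmenting tissues are not supported.
- Degenerate packings are handled by fallbacks (sliver dropping, membrane
  fallback vertices) that locally break watertightness; chemistry is
  protected by the lumping floors, but per-triangle adjacency around such
  defects is approximate.
- The explicit chemistry solver is the method being reproduced;
  it is O(L^2/D / dt) per quasi-steady solve and dominates runtime on
  large tissues.  No implicit or direct steady-state solver is provided by
  design.
- Absolute parameter values (µm/time units) are calibration, not fits to
  measurements; only derived dimensionless behavior (decay-length ratio,
  trend directions, schedule arithmetic) is meaningful.
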
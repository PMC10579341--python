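# Methods

## Model

The simulator is an Eden growth model on an L³ cubic lattice, modified with
rare long-range single-cell dispersal. The biological picture: a clonal
colony grows in a semi-dense gel that blocks sustained swimming; cells on
the colony surface divide into adjacent pore space, and occasionally a
sufficiently exposed cell breaks away, swims a short distance, is trapped
again, and founds a satellite cluster. Because swimming episodes are fast
compared with the division time, dispersal is modelled as an instantaneous
jump, not a trajectory.

State and events:

* Occupancy is binary (≤ 1 cell per site; 1 site ≈ 1 μm³ ≈ 1 cell volume).
* A cell with ≥ 1 of its six face-neighbours empty can divide (rate `k`);
  cells with zero empty face-neighbours are inert.
* A cell with ≥ `n2_min_empty` (default 4) empty face-neighbours can
  additionally jump (rate `k_s`). These two classes are the populations N1
  (divide-only) and N2 (divide-or-jump).
* Division places the daughter on a uniformly chosen member of the surface
  array — the set of empty sites face-adjacent to the colony. Note the
  *rate* of division is per surface cell while the *placement* is per
  surface site; the two populations are different objects.
* A jump displaces the cell by `round(N(0, σ²I₃))` (component-wise rounding
  to the nearest site). Occupied targets — including the origin itself,
  which the mover still holds during the draw, and anything outside the
  lattice — trigger a full redraw of the three components.

Time advances by exact Gillespie sampling: `T = N1·k + N2·(k + k_s)`,
`τ = −ln(r)/T` with `r ~ U(0,1)` (a zero draw is rejected), and the event
class is division with probability `(N1 + N2)·k/T`. The run starts from one
cell at the lattice centre, with `t = 0`, and stops at the event budget, on
a jam (`T = 0`, impossible from a single-cell start but handled), or when
any cell is placed within `boundary_margin` sites of the lattice edge
(status `truncated`; default margin `max(⌈3σ⌉, 5)` so the Gaussian tail
cannot feel the closed walls).

## Parameters

| Parameter | Units | Default | Meaning |
| --- | --- | --- | --- |
| `k` | 1/time | 1 | division rate; fixes the time unit |
| `k_s` | 1/time | 0 | jump rate of N2 cells; study grid {0.001, 0.05, 0.1, 0.2} |
| `sigma` | sites (μm) | 0 | SD of the Gaussian jump; study grid {2, 5, 7, 10} |
| `L` | sites | 301 | lattice edge; 301 holds a 10⁶-event compact run |
| `max_events` | – | 10⁶ | total division + jump budget |
| `n2_min_empty` | – | 4 | empty neighbours required to jump (3 selectable) |
| `boundary_variant` | – | dedup | surface sites unique, or weighted by adjacency |
| `boundary_margin` | sites | max(⌈3σ⌉, 5) | edge guard band |
| `redraw_cap` | – | 10⁴ | jump redraws before the jump is abandoned |

## Two engines, one random stream

`run` keeps all bookkeeping incremental: per-site occupancy and occupied-
neighbour counts, scalar N1/N2 counters, and two Fenwick (binary indexed)
trees storing the sampling weights of the surface array and of N2. Rank
selection in a Fenwick tree equals indexing into the lexicographically
sorted member list, so uniform selection is representation-independent.
`run_naive_oracle` rebuilds the classification and the sorted surface array
from scratch every event. Both consume the shared random stream in a fixed
per-event order (waiting-time draw, event-class draw, then event-specific
draws), so identical `(params, seed)` give bit-identical event logs from
both engines — the equivalence is asserted in the tests across the Eden
limit, jump runs, the `n2_min_empty = 3` reading and the multiplicity
surface variant. The heavy per-event updates are numba-compiled; a 10⁶-event
run takes ~10 s on one CPU.

Per-event rate bookkeeping is O(log L³); event logs store type, clock,
waiting time, total rate and sites for audit (the normalised waiting times
`τ·T` are checked against the standard exponential).

## Morphology pipeline

Applied identically to voxel stacks and to simulated lattices (rendered as
binary stacks with a 2-voxel pad; thresholding is skipped for binary
input):

1. **Otsu threshold** (grayscale input): 256 equal-width bins over the
   observed range; foreground strictly above the threshold, so a two-valued
   image separates exactly.
2. **Optional half-colony crop**: the cut plane passes through the main
   object's centre of mass along a chosen axis; `lower`/`upper` partition
   the foreground exactly. This mirrors discarding the depth-distorted half
   of a confocal stack; the small-object filter runs *after* the crop.
3. **Small-cluster filter**: components below 11 μm³ (configurable) are
   removed; a component of exactly 11 μm³ survives. Volumes are physical,
   so anisotropic voxels (e.g. 1.52 × 1.52 × 1.33 μm) are handled.
4. **Labelling**: 26-connectivity by default (6/18 selectable); labels are
   renumbered by first raster occurrence, making them deterministic across
   backends.
5. **Metrics**: volume = voxel count × voxel volume; COM = unweighted mean
   of voxel centres in μm; convexity = voxel count / voxels in the convex
   hull image (hull of surface-voxel centres, counted by an exact
   per-column interval test). This is the regionprops/BiofilmQ solidity
   convention: any convex digitised solid scores exactly 1. Objects of ≤ 4
   voxels or with degenerate (coplanar) hulls are assigned convexity 1 and
   flagged.
6. **Report**: the largest object (ties → smallest label) is the main
   colony; every other component is a satellite. Satellite volumes,
   COM-to-main distances and per-object nearest neighbours (COM-to-COM; a
   surface-to-surface variant is deliberately not implemented) are
   reported.

## Synthetic fixtures

`fixtures.make_stack` renders a grayscale stack with exact ground truth: an
ellipsoidal main colony (default semi-axes 30/33/36 μm ≈ 1.5·10⁵ μm³),
spherical satellites (default 5, radii 2.5–4 μm, 80–125 μm from the centre),
additive Gaussian noise (default SD 18 against a 180-intensity object/
background separation, i.e. 10 noise SDs) and isolated single-voxel speckle
below the 11 μm³ filter. A voxel is foreground when its centre lies inside
the analytic solid; objects are rejected at generation time if they come
within one voxel of each other, so they can never merge under
26-connectivity. What the fixtures do **not** emulate: the microscope PSF,
depth-dependent attenuation, photobleaching, or textured object interiors —
passing the recovery tests therefore demonstrates correctness of the
pipeline's geometry and counting, not robustness to real optics.

## Study design helpers

* `run_sweep` executes a σ × k_s grid with seeded replicates
  (seed = base + cell·replicates + replicate), analyses every colony, and
  aggregates satellite counts, volume distributions (with coefficient of
  variation) and a regime label per cell.
* Regime labels: *dispersed* when the main object holds < 50 % of the
  filtered volume, *compact* when satellites < 0.5 on average, *satellite*
  otherwise. The thresholds are configuration, not biology.
* `population_curve` resamples the population step functions of replicates
  on a common uniform grid (up to the earliest finishing replicate) with
  mean ± SD bands.
* `growth_exponent` fits log N against log t over the final half of the
  time range (window configurable) and reports the slope with R², plus the
  R² of the semi-log fit for discriminating constructed exponential input.

## Numerical choices and degenerate inputs

* Simulation sizes in the test suite: 10 replicates × 10⁵ events per grid
  cell on L = 351 (≈ 1 s per run), and a single 10⁶-event width check on
  L = 301; the acceptance script uses 3 × 10⁶-event runs.
* Random numbers: `numpy.random.default_rng(seed)` everywhere; sweep and
  fixture seeds are derived arithmetically so any single run is
  reconstructable.
* `τ` accrues before the event is applied; `t` starts at 0.
* Aborted jumps (redraw cap hit, practically impossible for σ ≥ 2) advance
  the clock, consume an event slot and leave the state unchanged.
* Empty morphology input after filtering yields an empty report
  (`main_id = None`), not an error; a constant-intensity stack refuses to
  threshold, naming the condition.
* Convexity can only reach 1 + ε with ε = 0 under the voxelized-hull
  definition; the hull membership test uses a 10⁻⁷ relaxation so boundary
  voxels are never dropped by rounding.

## Known limitations

* The model has no nutrient field, no mechanics (cell shape, adhesion, gel
  elasticity) and no explicit swimming trajectories; jumps are
  instantaneous and their distribution is time-invariant.
* At desk-scale budgets (≤ 10⁶ events) the colony front advances ~3–4
  sites per division time because the Eden growth zone is several sites
  thick; the equivalent-sphere radius is linear in time only after a lag
  comparable to the run length. Late-time log N–log t slopes therefore sit
  well above the asymptotic value 3 in the Eden limit, approaching it only
  slowly as the budget grows.
* Under every tested reading of the model (both N2 thresholds, both
  surface-weighting variants, 6/18/26 connectivity) the largest connected
  component keeps the majority of the biomass even at σ = 10, k_s = 0.2:
  satellites are annexed by the advancing front faster than they escape.
  "Spreading" shows up as low main-object convexity (~0.3) and large
  extent rather than as fragmentation of the volume majority, so the
  *dispersed* regime label (main < 50 %) is not reached at these scales.
* Satellite identity is purely geometric (connected components); merging
  and re-detachment histories are not tracked.
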
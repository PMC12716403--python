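# Methods

## Model

Cells are disk-like agents with radius *R* in a square, periodic 2-D domain
of side *L*. Agent *i* carries a position `r_i(t)` and a heading
`theta_i(t)`. Two ingredients drive the dynamics: pairwise mechanical
interaction and noisy protrusion-driven active motion.

**Pair force.** For minimum-image center distance *d* and surface gap
`g = d - (R_i + R_j)`, the force on *i* from *j* is

```
F_ij = s(g) * F_base_eff * exp(-|g| / alpha) * n_ij,     d <= r_cut
```

with `n_ij` the unit vector from *j* toward *i*, `s(g) = +1` (repulsion) for
overlapping disks and `-1` (adhesion) out to the cutoff, and zero beyond
`r_cut`. The magnitude is maximal at contact and decays with the gap — a
bounded, short-range law; an exponentially *growing* form would be unphysical.
`F_base_eff = F_base * leader_factor` when either agent is a leader. The law
is exactly antisymmetric, so total interaction momentum is conserved.

**Heading dynamics.** The direction of motion integrates three torques:

```
theta <- theta + align_rate * dt * wrap(angle(F_i) - theta)        (net force)
               + heading_align * dt * wrap(<theta>_nbrs - theta)   (consensus)
               + noise_eta * sqrt(dt) * xi,   xi ~ N(0, 1)         (noise)
```

The first term steers cells along the net mechanical cue (skipped when
`F_i = 0`); the second relaxes the heading toward the circular-mean heading
of neighbors within `r_cut`, representing the directional consensus of
mechanically coupled cells that migrate as multicellular strands; the third
is rotational diffusion. Without the consensus term, clusters held together
by adhesion stall — the net force inside a balanced cluster is centripetal
and carries no direction — and no collective strand migration emerges. With
it, adhesion-bound trains of cells migrate persistently and carve shared
channels, which is the experimentally observed mode of channel extension.

**Force-activated motility (mechanotransduction).** The overdamped position
update is

```
r <- r + v_eff * (cos theta, sin theta) * dt + mobility * F_i * dt
v_eff = v0_base * (1 + mech_gain * min(max(|F_i| - mech_thresh, 0), mech_sat))
```

where `v0_base` is `v0` (times `leader_factor` for leaders). Cells that sense
an interaction force above `mech_thresh` up-regulate their protrusion speed,
saturating at `mech_sat`; unstimulated cells barely move. This models the
integrin–RhoA/YAP-type mechanotransduction loop by which tensile cues
transmitted between cells activate migration. It is essential for the
interaction-force phenomenology: with force entering only through transport
(`mobility * F_i`), raising the force scale merely aggregates and stalls
agents, and network formation *decreases* with force — opposite to the
observed behavior. With thresholded force-activated motility, a low force
scale leaves cells sub-threshold (scattered cell-sized pockets), while
higher force scales recruit progressively more cells into fast, collective,
channel-forming migration.

**Update scheme.** Synchronous: all forces are evaluated from the pre-step
state; agents then update in id order with one Gaussian draw per agent per
step from a single seeded generator, so identical configurations reproduce
byte-identical trajectories. Coincident centers (probability zero, but
possible in hand-built states) are resolved by nudging the higher-id agent
1e-6 µm along a seeded random direction, with a warning. Neighbor
enumeration uses a periodic k-d tree (`scipy.spatial.cKDTree` with
`boxsize`), contractually identical to all-pairs minimum-image search and
tested against it.

## Default parameters (the study conditions)

| parameter | value | units | meaning |
|---|---|---|---|
| L | 500 | µm | domain side (periodic) |
| n_agents | 200 | – | cell count |
| R (`agent_radius`) | 4 | µm | cell disk radius = channel half-width |
| v0 | 0.02 | µm/t | baseline (unstimulated) protrusion speed |
| F_base | 1.0 | nN | force scale; order of measured inter-channel bridge tension |
| alpha | 10 | µm | force decay length |
| r_cut | 30 | µm | interaction cutoff (center-to-center) |
| mobility | 1.0 | µm/(nN·t) | inverse friction with the matrix |
| align_rate | 1.0 | 1/t | heading relaxation toward net force |
| heading_align | 1.0 | 1/t | heading relaxation toward neighbor consensus |
| mech_gain | 10 | 1/nN | motility gain per sensed nN above threshold |
| mech_thresh | 0.4 | nN | mechanotransduction activation threshold |
| mech_sat | 2.0 | nN | sensed-force saturation |
| noise_eta | 0.3 | rad/√t | rotational noise |
| leader_factor | 2.0 | – | leader multiplier on F_base and v0 |
| dt | 0.1 | t | time step |
| n_steps | 5000 | – | steps (500 time units) |
| record_every | 25 | – | frames every 2.5 t |

The time unit *t* is arbitrary (≈ minutes at these speeds). The defaults were
fixed once, by physical-realism criteria evaluated on rendered masks — the
control (middle-force) condition must produce sparse, strand-like,
partially connected channel networks occupying roughly 15–45 % of the field
across the force ladder, with channels of width ~8 µm, matching the
qualitative appearance of 3-D collagen channel networks — and are
deliberately *not* calibrated to any measured quantity. With wider/faster
agents (e.g. R = 10 µm, v0 = 0.5) the accumulated masks become
space-filling foams whose skeletons measure coverage holes instead of
channels, and all force trends invert; that regime was rejected on realism
grounds. At the chosen `dt`, per-step displacements stay well below one
radius (asserted in tests).

## From trajectories to channel masks

Channels never close, so the occupancy map is the union of all swept disks.
Consecutive recorded positions of an agent are joined by a capsule (segment
dilated by `channel_radius`, default = agent radius); capsules crossing the
periodic boundary are unwrapped and stamped on both sides. Numerically, each
segment is sampled at spacing ≤ min(pixel_size, channel_radius)/2 and each
sample stamps an exact pixel-center-in-disk test; the sampling error at the
capsule boundary is ≤ s²/(8·R) ≈ 0.01 µm — far below the 2 µm pixel — and
the disk case is exact. Default pixel size 2 µm gives a 250×250 grid for the
500 µm domain: it resolves the 8 µm channels while keeping skeletonization
fast. Masks are written as 0/255 single-page TIFF with a JSON sidecar
(`pixel_size_um`, `domain_size_um`); PNG is accepted on read.

## Skeleton topology

Masks are skeletonized with a topology-preserving thinning
(`skimage.morphology.skeletonize`; components and holes are preserved —
asserted on fixtures). Pixel adjacency is 8-connected with redundant
diagonals dropped (a diagonal step is kept only when neither orthogonal
pixel it cuts across is set), which makes the pixel graph's cycle rank equal
the mask's hole count; background holes are implicitly 4-connected — the
standard digital-topology pairing.

Skeleton pixels with one (reduced) neighbor are endpoints; pixels with ≥ 3
neighbors are node pixels, and 8-connected clusters of node pixels merge
into single junction vertices. Maximal degree-2 paths become edges with
geodesic length Σ(1 or √2) × pixel size; junction-free closed loops are
kept as self-loop edges on cycle-anchor vertices; isolated single pixels are
dropped. Classification follows the tube-formation convention: a *branch* is
an edge with ≥ 1 endpoint; a *segment* joins two junctions; a *master
junction* is incident to ≥ 3 segments (branches excluded); a *master
segment* is a segment both of whose junctions carry ≥ 2 other
segments-or-cycles; *meshes* are independent cycles, counted as
`E − V + C` on the condensed multigraph (asserted against networkx on every
fixture); *nodes* (reported as `n_nodes`) are raw skeleton pixels with ≥ 3
8-neighbors, the pre-merge pixel count.

Derived scores (the named scores have no published formulas, so these are
this package's fixed definitions):

- **stability** – length in the largest connected component / total length;
- **complexity** – (junctions + meshes) per 10⁴ µm² of channel area;
- **tortuosity** – mean over edges of geodesic length / endpoint chord
  (cycles and self-loops excluded);
- **redundancy** – cycle rank / E (0 when E = 0);
- **robustness** – mean over seeded trials (default 200) of the length
  fraction retained in the largest component after removing
  `round(0.1·E)` random edges (1.0 when that rounds to zero); validated
  against exhaustive single-edge-removal enumeration in tests;
- **average degree** – 2E/V on the condensed graph.

Empty graphs report counts of zero and *missing* (NaN) ratio scores, never
fake zeros. Spur pruning removes terminal branches shorter than a threshold
before classification: the module default is 2 px (bare skeletonization
artifacts), while the experiments pipeline uses 8 px ≈ 2× the channel width
— a skeleton fragment shorter than twice the channel's own width is a
cell-sized pocket or wall roughness, not a resolvable channel. Without this
minimum-feature rule, low-force fields register ~170 spurious one-blob
"branches" that swamp the branch statistics.

## Migration metrics

Per track: cumulative path length S, net displacement D, mean velocity S/T,
straightness D/S ∈ [0, 1] (undefined when S = 0, reported missing). Tracks
from periodic simulations are unwrapped first (any per-axis step > L/2 is a
boundary crossing). D ≤ S is asserted on every simulated cohort, and
straightness is invariant under rigid motions (property-tested).

## Synthetic fixtures

Mask fixtures draw named one-pixel motifs (line, plus, H, ring, theta,
2×2-cell lattice, two equal components) and dilate them by a disk, so the
skeleton recovers the motif and every count is known by construction (e.g.
theta: 2 junctions, 3 segments, cycle rank 3 − 2 + 1 = 2 meshes). Track
fixtures carry closed-form S/D/straightness (3-4-5 path → 5/7). They emulate
the *topology* and *kinematics* of real channel data, not its appearance: no
collagen texture, no intensity noise, no segmentation step. Passing the
fixture suite therefore validates the graph/metric machinery exactly, but
says nothing about segmentation of real confocal images, which is out of
scope.

## Experiments and statistics

Each experiment runs condition × replicate pipelines (simulate → rasterize →
topology + migration) with seed
`(seed_base + (crc32(label) % 100003)·n_replicates + r) mod 2³¹`, recorded
in a manifest. Hypothesis tests are seeded permutation tests with no
distributional assumptions: the force-sweep trend uses Spearman rank
correlation between condition rank and metric (9999 permutations, one-sided);
group comparisons use the difference of means, with exact enumeration of all
assignments when C(n, n_a) ≤ 20000. Note that with tie-ranked condition
labels the attainable maximum of Spearman's rho is < 1 (≈ 0.95 for 3×3
perfectly ordered data).

Study designs at the defaults: force sweep `F_base × {0.25, 1, 2}`
(low/middle/high, the contractility-ladder analogue), 10 replicates; leader
comparison `leader_fraction 0.15, leader_factor 2` vs no leaders, 10
replicates; cell-line panel with bundled presets ordered MCF-10A < T47D <
MCF-7 < MDA-MB-231 in force scale, speed and leader fraction (the
MDA-MB-231 leader fraction of 0.16 follows the ~16 % leader share measured
in single channels; otherwise the presets are qualitative orderings, not
calibrations), 5 replicates; time course at cumulative-frame checkpoints
{50, 100, 150, 200} of a single run per replicate (occupancy is nested by
construction).

## Known limitations

- The model is 2-D; real channel networks are 3-D.
- Matrix mechanics are implicit: no collagen fibers, no bridge stiffness
  field, no degradation chemistry — mechanical communication enters only
  through pairwise forces and the motility coupling.
- Parameters are not calibrated to AFM/optical-tweezer measurements; only
  orders of magnitude and qualitative regime were matched.
- The node-interval spacing is force-stable only between network-forming
  conditions (middle vs high force agree within noise); the low-force
  condition is a fragmented-pocket regime whose spacing statistic measures
  pocket geometry instead, and sits lower.
- Skeleton metrics saturate once channel coverage approaches ~50 % of the
  field; comparisons are meaningful in the sparse-network regime the
  defaults target.
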
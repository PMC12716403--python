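# channelnet

Migrating cancer cells do not just squeeze through the extracellular matrix —
they carve lumenized *microchannels* into it, and mechanically coupled cells
merge those tracks into an interconnected channel network that serves as a
low-resistance highway for invasion. `channelnet` is a small research package
for studying that process in silico. It provides, as one tested pipeline:

1. **An off-lattice agent-based model** of disk-like cells in a periodic 2-D
   domain. Cells interact through a short-range exponential pair force
   (repulsive in overlap, adhesive out to a cutoff), move overdamped with a
   protrusion speed plus mobility times the net force, align their heading
   toward the net force and toward their neighbors' mean heading, carry
   rotational noise, and up-regulate their motility when the sensed
   interaction force exceeds a mechanotransduction threshold. A *leader*
   subpopulation gets its force scale and protrusion speed multiplied.
2. **Trajectory rasterization**: because channels are carved irreversibly,
   the accumulated agent trajectories (dilated to the channel radius) are the
   channel map — a binary occupancy grid written as TIFF + JSON sidecar.
3. **Skeleton-graph topology**: skeletonization, junction/endpoint graph
   extraction, and the tube-formation vocabulary — nodes, junctions, master
   junctions, branches, segments, master segments, meshes — plus derived
   network scores (stability, complexity, tortuosity, redundancy, robustness,
   average degree).
4. **Migration metrics** per track: cumulative distance S, displacement D,
   mean velocity, and straightness D/S.
5. **In-silico experiments** with seeded permutation statistics: an
   interaction-force sweep, a leader vs no-leader comparison, a four-cell-line
   panel (MCF-10A, T47D, MCF-7, MDA-MB-231 presets), and a time course.

The model's core quantities: the pair force between cells *i* and *j* has
magnitude `F_base * exp(-|g|/alpha)` along the center line, where
`g = d - (R_i + R_j)` is the surface gap; the net force is
`F_i = sum_{j in NN(i)} F_ij` over neighbors within `r_cut`; the heading
obeys `theta += align_rate*dt*wrap(angle(F_i) - theta)
+ heading_align*dt*wrap(mean_heading_nbrs - theta) + noise_eta*sqrt(dt)*xi`;
and the position advances by `v_eff*(cos theta, sin theta)*dt
+ mobility*F_i*dt` with
`v_eff = v0*(1 + mech_gain*min(max(|F_i|-mech_thresh,0), mech_sat))`.
See `docs/methods.md` for the full model description and parameter table.

## Worked example

```python
from channelnet import (SimConfig, run_simulation, rasterize_trajectories,
                        analyze_mask, cohort_metrics)

config = SimConfig(seed=42, leader_fraction=0.15)
traj = run_simulation(config)                     # 200 cells, 5000 steps
grid = rasterize_trajectories(traj)               # 250x250 binary mask
metrics, graph = analyze_mask(grid, prune_px=8)   # skeleton topology
per_track, summary = cohort_metrics(traj)
```

which prints (via the metric fields):

```
channel area: 100680 um^2 (40% of the field)
junctions: 113  (master: 66)
branches: 73   segments: 141
meshes: 37       total length: 6701 um
stability: 0.37  redundancy: 0.17 robustness: 0.27
mean straightness D/S: 0.41
```

Read: after 500 time units, the 200 cells (15% leaders) carved channels
covering 40% of the 500 µm field; the skeletonized network contains 113
junction clusters, 37 closed meshes and 6.7 mm of channel; 37% of the network
length sits in the largest connected component, and removing a random 10% of
edges keeps on average 27% of the length connected. The mean track
straightness of 0.41 reflects cells that alternate directed channel-following
runs with turns at junctions.

The same stages are exposed on the command line:

```sh
channelnet simulate --out traj.csv --seed 42 --override leader_fraction=0.15
channelnet trace --traj traj.csv --out mask.tiff --pixel-size 2
channelnet topology --mask mask.tiff --out-prefix results/run1 --prune 8
channelnet metrics --traj traj.csv --out-prefix results/run1
```

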
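# Methods

## Problem and model

Adaptive MD protocols such as supervised molecular dynamics produce long
ligand-pose trajectories in which a ligand repeatedly visits a handful of
metastable binding modes inside a protein site, with excursions away from the
site. `pscore` turns such a trajectory (plus a table of per-snapshot
protein–ligand interaction energies) into a ranked list of binding modes:

1. **Proximity filtration.** Frames whose ligand sits more than a cutoff
   distance from the binding-site center are discarded as unbound. The
   default cutoff is 9 Å; a frame at exactly 9 Å is retained (only frames
   *beyond* the cutoff are unbound). The distance is measured between the
   ligand heavy-atom centroid and the site center (the centroid of the
   user-supplied site atoms); a minimum-atom-distance mode is available
   behind a flag for elongated ligands.
2. **Binding-mode clustering.** DBSCAN over pairwise ligand RMSD with
   eps = 1 Å and a minimum of 100 similar conformations per mode. RMSD is
   computed on heavy atoms **without superposition**: a pose is a position
   *and* orientation of the ligand relative to the site, so frames are never
   re-fitted onto each other. Coordinates must therefore arrive already
   expressed in the protein frame — the package never aligns trajectories.
3. **Residence time.** Each mode's residence time t is its member count
   times the frame spacing (20 ps per frame by default), in ns.
4. **Interaction energy.** Per-snapshot energies are consumed as tables —
   either a single total (e.g. an MM-PBSA end-point estimate) or the five
   PIEDA terms (electrostatic, exchange repulsion, charge-transfer + mixed,
   dispersion, solvation), which are summed per snapshot. A mode's energy
   ΔE is the **dynamical average**: the arithmetic mean over snapshots
   subsampled from the cluster every 2 ns of simulation time (mode `da`),
   or the single representative-frame energy (mode `single`). The
   representative is the cluster medoid (minimum summed RMSD to the other
   members). N in the average is the number of extracted snapshots, not the
   full member count — energies exist only at extracted snapshots, and they
   are never interpolated.
5. **P-score.** With extremes min ΔE / max ΔE over the compared set and T
   the total simulation time,

       P_i = (1 + max ΔE − ΔE_i) / (1 + max ΔE − min ΔE) × t_i / T.

   P lies in [0, 1], is 1 exactly when t_i = T and ΔE_i = min ΔE, is
   strictly monotone in both descriptors, and is invariant to a uniform
   energy shift and to a common rescaling of all times. The +1 offsets keep
   the affinity factor positive at max ΔE. Among the candidate rescalings
   of the two descriptors, this is the unique form with all four of those
   properties, which is why it is the one implemented.
6. **Quadrant classification.** Each entry is placed by min–max-normalized
   residence time (x) and normalized affinity (y, 1 at the lowest energy)
   relative to the *means* of the two normalized axes over the whole set.
   Top-right = long-lived and strongly bound → candidate poses. An entry
   within `mean_line_tol` (default 0.02 normalized units) of either mean
   line is flagged `border_line`: more sampling is recommended before
   trusting the call. A ligand with no entry in the top-right quadrant gets
   the explicit verdict **NA** — a first-class result, not an error.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `frame_dt_ps` | 20 | ps | frame spacing of the upstream sampling protocol |
| `cutoff_A` | 9.0 | Å | unbound threshold; strict `>` removes |
| `eps_A` | 1.0 | Å RMSD | same-pose similarity radius |
| `min_pts` | 100 | frames | minimum conformations per binding mode; counts the point itself, boundary distance = eps is inside |
| `interval_ns` | 2.0 | ns | snapshot spacing for dynamical averaging |
| `total_time_T_ns` | — | ns | total simulation time; must bound every t_i |
| `extremes_scope` | campaign | — | min/max ΔE over all compared entries; `per_ligand` and `fixed` available |
| `mean_line_tol` | 0.02 | norm. units | half-width of the border band |
| `temperature_K`, R | 298.15, 1.9872e-3 | K, kcal/(mol·K) | for ΔG_exp = R·T·ln IC50 |

`extremes_scope="campaign"` is the default because the extremes are defined
over all compared poses or ligands jointly — that is what makes scores
comparable across ligands — and because sensible trade-off rankings (a
long-lived 262 ns mode over a slightly lower-energy 51 ns mode, as in the
README example) only emerge with campaign-wide extremes: a narrow
per-ligand span inflates the affinity factor until small energy differences
dominate. `fixed` lets callers score a subset against extremes established
by a wider campaign. Quadrant means are likewise computed jointly over the
comparison set.

Because min ΔE, max ΔE and T all enter the score, P-scores are only
comparable between runs that share those three quantities; when comparing
against scores computed elsewhere, reconstruct them with `fixed` extremes
rather than assuming the values transfer. T is an explicit parameter and
should normally be the configured total simulation time (e.g. 600 ns for
three 200 ns replicates) even after filtration; callers who prefer the
retained (post-filter) time as denominator simply pass that instead.

## Deterministic tie-breaks and degenerate inputs

- Border points reachable from several core clusters join the cluster of
  their lowest-indexed core neighbour; cluster component labels follow the
  smallest core index, so clustering is deterministic for a fixed input and
  invariant (up to relabeling) under frame reordering.
- Cluster ids C-01, C-02, … are ordered by descending residence time, ties
  by smaller representative frame index. Medoid ties take the
  smaller frame index.
- Top-pose ties: higher P-score, then longer residence time, then lower
  energy, then lexicographic cluster id.
- Degenerate normalizations (single entry, equal extremes) map to 1.0; a
  single-entry comparison is trivially top-right/high since there is nothing
  to compare against.
- An all-frames-filtered trajectory yields an empty cluster list and an NA
  verdict downstream, never an exception.
- Snapshot subsampling walks each replicate's own timeline; intervals are
  never measured across the concatenation seam. On concatenation, global
  frame ids are offset per replicate so that energy tables can key on a
  single integer.

## Numerical choices

Pairwise RMSD for clustering-scale inputs (≤ 4000 frames) is computed by
direct coordinate differences (exact, symmetric by construction). Larger
trajectories avoid the quadratic matrix entirely: unsuperposed RMSD is an
exact Euclidean metric on flattened coordinates scaled by 1/√n_atoms, so
neighbour counts, core-component expansion and medoids are computed with
cache-tiled float32 Gram-trick kernels (a 10⁻⁶ slack on the squared radius
absorbs the reduced precision at the eps boundary) with float64
accumulation. Both paths implement identical semantics and are
cross-checked against each other and against an exhaustive reference in the
test suite. Pearson r/p-values come from `scipy.stats.pearsonr`
(t-transform, n − 2 df), R² from `scipy.stats.linregress`, and
cluster-to-truth matching in the benchmark from
`scipy.optimize.linear_sum_assignment`.

## Synthetic benchmark: what it emulates, and what it does not

The generator plants K metastable poses (rigid pseudo-atom template +
isotropic Gaussian coordinate noise, σ = 0.25 Å so within-pose RMSD ≈
√6·σ ≈ 0.6 Å stays under eps), an unbound state placed at twice the cutoff
so filtration is deterministic, per-frame energies drawn
Normal(pose mean, sd), and a sticky first-order Markov chain over the
states whose stationary distribution equals the requested occupancies
(per-frame switch probability 0.02 → mean sojourn 1 ns at 20 ps/frame, so a
30,000-frame run holds ~600 sojourns and occupancy estimates concentrate
within a few percent). Feasibility is checked empirically at generation
time: within-pose RMSD below eps with probability > 0.99, template
separation > 2 × eps.

The canonical two-pose benchmark (dwell 0.6/0.3, unbound 0.1, energies
−120/−100 kcal/mol, 30,000 frames) is the package's recovery condition:
both modes recovered, dwell fractions within ±0.05, energy means within 3
standard errors, dominant pose selected, in ≥ 19/20 seeds.

What the generator deliberately does *not* emulate: force-field physics,
binding/unbinding kinetics, conformational (internal) ligand flexibility,
anisotropic or correlated coordinate noise, energy–coordinate correlation
within a pose, and the supervision logic of adaptive sampling itself.
Passing recovery tests therefore demonstrates the *pipeline's* correctness
on data satisfying its stated assumptions (well-separated, well-populated
modes), not predictive power on real MD output.

## Known limitations

- No symmetry-corrected RMSD for topologically symmetric ligands; the
  explicit atom-pair mapping covers partial-scaffold comparisons.
- Binary MD formats (DCD/XTC) are out of scope; multi-model PDB and
  extended XYZ are the supported trajectory carriers.
- The ΔG_exp-based experimental P-score uses the same +1-offset rescaling
  as the pose score (a plain min–max variant would differ); IC50 must be
  molar after unit conversion, and cross-ligand comparability assumes a
  shared assay.
- Whether solvation is included in per-snapshot totals is the caller's
  choice; the energy schema records which table form was used.
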
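# hfnca

**Structure-parameter importance for hyperfine coupling constants via
regularized neighborhood components analysis.**

Hyperfine coupling constants — the electron–nuclear interactions measured by
EPR spectroscopy — are set by a radical's entire electronic structure, which
in turn fluctuates with its geometry. Given a molecular-dynamics trajectory
of an organic radical and hyperfine tensors computed on snapshots along it,
`hfnca` quantifies *which* structural degrees of freedom (bond lengths, bond
angles, dihedral angles) drive *which* coupling constants, without assuming
any mechanism up front. The result is a per-molecule **importance matrix**
indexed by (structure parameter, tensor component, nucleus) that makes
relationships such as "A_iso of this hydrogen follows its own C–H bond and
the opposite H–C–H angle" directly visible.

The package is aimed at EPR spectroscopists and computational chemists who
have (or can generate) MD snapshots with per-snapshot hyperfine tensors, and
ships a synthetic-data generator so the entire statistical pipeline can be
exercised and validated without any quantum chemistry.

## Method

1. **Structure parameters.** Bonds are detected on the first trajectory
   frame (the optimized structure) as atom pairs closer than a 1.5 Å
   cutoff, and the topology is frozen thereafter. One bond angle is
   enumerated per neighbor pair at every atom, and exactly one dihedral per
   central bond with flanking neighbors. Each dihedral θ is encoded as
   (cos θ, sin θ) to remove the ±180° discontinuity; all feature columns
   are individually standardized (z-score by default).

2. **Neighborhood components analysis (NCA) for regression.** For features
   x_i and a response y_i (one of A_x, A_y, A_z, or A_iso = (A_x+A_y+A_z)/3
   for one nucleus), NCA learns one weight per feature of a diagonal metric

       d_w(i,j) = Σ_r w_r² |x_ir − x_jr|,

   under the soft-neighbor assignment p_ij ∝ exp(−d_w(i,j)/σ), by minimizing
   the expected leave-one-out regression loss plus a ridge penalty

       f(w) = (1/n) Σ_i Σ_{j≠i} p_ij |y_i − y_j| + λ Σ_r w_r².

   Minimization uses L-BFGS-B with the analytic gradient. |w_r| is the
   importance of feature r; λ (default 0.05, or fourfold cross-validated)
   shrinks uninformative weights to zero.

3. **Importance matrix and symmetry diagnostics.** One independent fit per
   (component, nucleus) fills the 3-D importance matrix. Magnetically
   equivalent nuclei must show identical importance patterns up to a column
   permutation; two descriptors quantify deviations (a permutation-aligned
   cumulative MSE across equivalent nuclei, and a within-block standard
   deviation for equivalent features of a single nucleus) and serve as
   ground-truth-free quality gauges of the dataset.

## Worked example

Synthesize a methyl-radical trajectory whose hydrogen couplings depend
(negatively) on their own C–H bond and (positively) on the opposite angle,
then recover that pattern:

```python
import hfnca as h

truth = h.default_ground_truth("methyl", seed=0)
frame0 = h.make_idealized_geometry("methyl")
traj = h.simulate_trajectory(frame0, truth, n_frames=500, seed=0)
topology = h.build_topology(traj[0])          # bonds/angles/dihedrals from frame 0
series = h.evaluate_series(traj, topology)    # per-frame structure parameters
features = h.make_feature_table(series)       # trig expansion + z-scoring
responses = h.simulate_responses(features, truth, seed=1)

matrix = h.build_importance_matrix(features, responses, lam=0.05, seed=0)
print(matrix.slice("A_iso").round(2))

spec = h.methyl_equivalence_spec(features.feature_labels)
print("H-group MSE:", round(h.group_mse_descriptor(matrix, spec), 4))
print("C1 block std:", round(h.block_std_descriptor(matrix, "C1", spec=spec), 4))
```

Output:

```
          H1    H2    H3    C1
H1C1    1.81  0.00  0.00  1.45
H2C1    0.00  1.80  0.00  1.46
H3C1    0.00  0.00  1.79  1.42
H1C1H2  0.00  0.00  1.64  0.00
H1C1H3  0.00  1.63  0.00  0.00
H2C1H3  1.61  0.00  0.00  0.00
H-group MSE: 0.0021
C1 block std: 0.0105
```

Each hydrogen's A_iso column peaks at its own bond (H1 ← H1C1 …) and at the
angle not involving it (H1 ← H2C1H3), while the carbon column loads on all
three bonds equally — exactly the planted dependency structure, recovered
blind by the NCA fits. The near-zero group MSE and block standard deviation
confirm that the three equivalent hydrogens produced near-identical
importance patterns.

The same pipeline is scriptable from the shell:

```sh
hfnca simulate --radical methyl --n-frames 2000 --seed 1 --out run/
hfnca extract  --trajectory run/trajectory.xyz --out run/topology/
hfnca matrix   --trajectory run/trajectory.xyz --responses run/responses.tsv \
               --seed 1 --out run/matrix/
```

Real trajectories enter the same way: a multi-frame XYZ file plus a
tab/comma-delimited table with columns `snapshot, nucleus, A_x, A_y, A_z`
(MHz).

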
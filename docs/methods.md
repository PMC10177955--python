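# Methods

This note records the model, the parameter choices, the behavior of the
synthetic-data generator, and the numerical conventions used throughout
`hfnca`, together with the design decisions made where several reasonable
options existed.

## Structure parameters

Topology is determined once, on the first trajectory frame, as all atom
pairs with Euclidean distance strictly below a cutoff (default **1.5 Å**)
and is frozen for the rest of the trajectory. Freezing avoids both spurious
bonds from transient close contacts later in the dynamics and dropped bonds
from transient stretches. The 1.5 Å default covers the C–H, C–C(aromatic),
C–O, O–O and O–H bonds of the small organic radicals the package targets;
it is configurable because ordinary sp³ C–C bonds (~1.54 Å) fall outside
it. No per-element covalent radii are used.

From the bond graph, one angle (i, j, k), i < k, is enumerated per
unordered neighbor pair at every vertex j (so an atom of degree d
contributes C(d, 2) angles), and exactly one dihedral per central bond
whose two endpoints both have another neighbor. Since all dihedrals sharing
a central bond are strongly correlated along a trajectory, keeping one per
central bond avoids redundant features. The terminal atoms of that one
dihedral are chosen deterministically: the lowest-index neighbor on each
side, advancing the far terminal when the two coincide (three-membered
rings) and skipping the bond when no valid choice remains. Any fixed rule
works equally well statistically; this one is order-stable and
reproducible.

Angles are reported in degrees in [0, 180] (clamped arccos of the
normalized dot product); dihedrals are signed torsions in (−180, 180]
computed with the atan2-of-cross-products construction. Degenerate
geometry (zero-length arm, collinear backbone) raises an error naming the
frame rather than emitting NaN, so corrupted frames are visible
immediately.

## Feature engineering

Dihedrals are circular, so each dihedral column is expanded into its
(cos, sin) pair before modelling; bonds (Å) and angles (degrees) pass
through unchanged. The feature count is therefore
|bonds| + |angles| + 2·|dihedrals|. An optional extra column sums all bond
angles — 360° exactly for a planar trigonal center, strictly less under
pyramidal distortion — which is a useful global gauge for methyl-type
radicals; it is off by default and appended last when enabled.

Each feature column is standardized individually so that a single
regularization strength is comparable across features of different units
and spreads. Two modes are provided: **z-score** (zero mean, unit standard
deviation; the default, appropriate for the near-Gaussian bond/angle
distributions of MD) and **min–max** (to [0, 1]). The mode and per-feature
parameters are recorded for the inverse transform. Constant columns cannot
be standardized and are dropped with a warning. Standardization is applied
after snapshot subsampling, so the statistics describe exactly the set of
points the model sees.

Snapshot subsampling mimics how hyperfine calculations are placed along an
MD trajectory: starting at frame 0, successive gaps are drawn i.i.d.
uniformly from an integer interval (default **[1, 80]** steps). Randomized
rather than regular spacing avoids aliasing with normal-mode oscillation
periods, which would systematically suppress the variance of particular
structure parameters.

## NCA regression

For standardized features x_i ∈ R^p and a scalar response y_i, the model
learns a diagonal metric d_w(i, j) = Σ_r w_r² δ_r(x_i, x_j) with
δ_r the per-feature absolute difference (squared difference available).
Point i selects a stochastic reference neighbor with probability
p_ij = exp(−d_w(i,j)/σ) / Σ_{k≠i} exp(−d_w(i,k)/σ), p_ii = 0, and the
objective is

    f(w) = (1/n) Σ_i Σ_{j≠i} p_ij · l(y_i, y_j) + λ Σ_r w_r²,

with l the absolute difference by default (squared available). The
gradient is the closed form

    ∂f/∂w_r = (2 w_r / (n σ)) Σ_ij p_ij δ_r(i,j) (L_i − l_ij) + 2 λ w_r,
    L_i = Σ_j p_ij l_ij,

verified against central finite differences in the test suite. The softmax
is computed with row-wise max subtraction, so duplicate rows (d = 0) and
huge distances are both safe.

Numerical choices:

* **Kernel width σ = 1** — the natural scale for standardized features; the
  exact loss/kernel of the original analysis tooling is not published, so
  σ, the distance form and the loss are all configurable, and conclusions
  are drawn from counts, symmetry and recovery properties rather than
  from absolute importance values.
* **Initialization: all weights = 1**, deterministic. Optional seeded
  multi-start (perturbed inits, best objective kept) is available but off
  by default; the planted-recovery tests pass from the deterministic init.
* **Optimizer: L-BFGS-B** with analytic gradient, gradient tolerance 1e-6,
  at most 200 iterations. Non-convergence returns the model with
  `converged=False` plus a warning instead of raising.
* **Importances are reported as |w_r|** — the sign of w_r is not
  identifiable since only w² enters the metric; w² reporting is a flag.
* **λ default 0.05**; cross-validation uses a 20-point logarithmic grid on
  [1e-3, 3] with seeded-shuffle fourfold splits, scoring held-out points by
  the soft-neighbor kernel predictor ŷ_i = Σ_j p_ij y_j under mean absolute
  error, ties broken toward the smaller λ.
* The O(n²) pairwise computation is intentional; target problem sizes are
  a few hundred to ~2000 snapshots with ≤ ~50 features.

## Importance matrices

A_iso is the mean of the three principal values (one third of the tensor
trace — the literal-trace reading is available via `compute_aiso`'s
definition site if ever needed). For every nucleus and every component
(A_x, A_y, A_z, A_iso) an independent NCA fit is run with the shared λ —
a single λ keeps importances comparable across the matrix — and a per-fit
seed derived from the base seed and a CRC of the (nucleus, component)
labels, making results reproducible and independent of fit order. Feature
snapshots and response snapshots must describe identical frame sets;
mismatches raise listing the offending ids.

## Symmetry descriptors

Magnetic equivalence is declared by the user (an `EquivalenceSpec`), not
inferred from topology. For a group of equivalent nuclei, each member's
importance column is permuted into a canonical ordering — for a methyl-type
hydrogen HX: own bond, remaining bonds (ascending), opposite angle (the one
not involving HX), remaining angles (ascending); features invariant under
the relabeling (e.g. the angle sum) keep their position. The **group MSE
descriptor** sums the mean squared differences of aligned columns over all
unordered member pairs and over the anisotropic components A_x, A_y, A_z
("cumulative" = summed, not averaged; with a fixed component set the two
differ only by a constant factor and the trend conclusions are identical).
The **block standard-deviation descriptor** averages, over components and
declared feature blocks, the within-block standard deviation of one
nucleus's importances, using the sample (n−1) convention — the convention
is stated because either is defensible; with fixed block sizes it only
rescales the descriptor. Both descriptors are zero exactly under perfect
symmetry and decrease (statistically) with growing snapshot counts, which
is what makes them useful dataset-quality gauges when true importances are
unknown. `methyl_equivalence_spec` builds the spec automatically for CH₃
centers; other molecules supply YAML.

## Synthetic data generator

The generator stands in for geometry optimization, ab initio MD and
hyperfine DFT, and defines the conditions under which the pipeline is
validated.

* **Geometries.** Idealized methyl (planar, C–H 1.08 Å), ethyl (C–C
  1.49 Å, sp² radical center, tetrahedral methyl), methyl peroxy (C–O
  1.44 Å, O–O 1.31 Å, C–O–O 111°) and planar *p*-benzosemiquinone
  (aromatic C–C 1.40 Å, C=O 1.25 Å, C–OH 1.36 Å, O–H 0.97 Å), with atom
  labels (H1…, C1…, O1…) fixed by file order.
* **Trajectories.** A breadth-first construction tree rooted at the
  highest-degree atom defines an independent internal-coordinate set
  (distance to parent, angle, torsion per placed atom). Each coordinate
  oscillates as a superposition of sine waves (3 modes, frequencies drawn
  from 0.01–0.2 cycles/frame, random phases, amplitude split by a Dirichlet
  draw) plus Gaussian jitter, emulating the quasi-periodic character of
  real MD structure parameters. Default amplitudes — **bonds ±0.1 Å, angles
  ±8°, torsions ±15°**, jitter 0.01 Å / 1° / 2° — sit between published
  low- and high-temperature MD spreads for small radicals. Cartesian frames
  are rebuilt by sequential NeRF placement anchored to the frame-0
  positions of the first atoms, so zero perturbation reproduces frame 0 to
  machine precision. Frame 0 of the emitted trajectory is the unperturbed
  reference structure, as in real MD output whose first frame is the
  optimized geometry.
* **Rings.** Ring-closing bonds are not tree edges; their lengths receive
  their own oscillating targets, enforced by least-squares refinement of
  the angles and torsions of the atoms on the tree path between the closure
  endpoints whenever the rebuilt closure deviates by more than 0.05 Å.
  (Torsions alone cannot close an in-plane gap of a planar ring, hence the
  angles participate; a quadratic prior keeps all refined coordinates near
  their programmed values.)
* **Topology guard.** Every frame is checked for bond breaking/forming:
  programmed bonds may stretch transiently up to 0.25 Å past the cutoff
  (an aromatic C–C of 1.40 Å with a ±0.1 Å spread legitimately brushes
  1.5 Å, just as in real MD — which is exactly why topology is frozen from
  frame 0), while non-bonded pairs must stay above the cutoff. Violations
  raise with advice to reduce amplitudes.
* **Responses.** Each response column is a declared linear combination of
  feature columns plus Gaussian noise (default sd 0.3 against unit-variance
  features in the ready-made truths). A dependency declared on A_iso is
  applied to all three principal components so the isotropic mean inherits
  it; components without planted signal are pure noise. The bundled methyl
  truth is exactly symmetric under hydrogen relabeling, which is what the
  symmetry-descriptor validation relies on.

What the generator does *not* emulate: anharmonicity and mode coupling,
temperature, realistic force constants, correlated bond–angle dynamics,
non-Gaussian coupling-constant distributions, and any actual spin physics —
responses are linear in the features by construction. Passing tests
therefore demonstrate that the statistical machinery recovers known planted
structure–response relationships at realistic geometric amplitudes and
sample sizes; they do not validate DFT-level hyperfine predictions.

## Problem sizes

The validation suite runs at desk scale by design: planted-signal recovery
at n = 500 snapshots and p = 6 features over 20 seeds; gradient checks on
50 random instances at n = 20; the semiquinone shape checks at 60
snapshots (52 independent fits over 46 features); and the symmetry-trend
comparison over 20 paired runs at N = 25 versus N = 500 snapshots. These
sizes sit inside the regime the method targets (a few hundred to a couple
of thousand snapshots) while keeping the whole suite at a couple of
minutes on one core.

## Known limitations

* Bond detection uses a single global cutoff; heavier elements or unusual
  bonds need a custom cutoff.
* Magnetic equivalence must be declared manually; no automatic detection
  from topology or dynamics.
* NCA importances are not effect sizes: they rank features within one fit
  and comparisons across fits rely on shared standardization and λ.
* Absolute importance values depend on the kernel/loss configuration;
  only relative patterns (and their symmetry) are interpreted.
* The O(n²) memory/time of the objective makes the method unsuitable for
  trajectories analyzed at every step; subsample first.
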
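# Methods

## The problem

An *ab initio* structure-prediction search minimizes an energy function
E(S) = W · E(S) — a weighted sum of K energy terms — by Metropolis Monte
Carlo over conformations S.  Whether the search reaches the native
structure depends less on the native being the global minimum than on the
size of the **native attraction basin**: the set of conformations from
which a downhill search reaches the native.  BARS (Broadening
Attraction-basin with Reverse Sampling) tunes the weight vector W so that
this basin grows, by alternating two procedures:

1. **Reverse Monte Carlo sampling.**  Starting from the native S₀, propose
   local moves and accept only strict energy increases.  The walk ends at
   an *edge point* Sₙ once `max_fail` consecutive proposals have failed to
   increase the energy — operationally, a conformation on the basin's
   ridge.  Each path S₀ → … → Sₙ has strictly increasing energies.  The
   RMSD between S₀ and Sₙ is a per-path measure of the basin radius; the
   mean over many paths (50 in the full protocol) is the reported radius.
   The edge point's m perturbation neighbors (m = 1000 in the full
   protocol) are retained as term vectors.

2. **Weight tuning by linear program.**  Find new weights W minimizing
   ‖W − W₀‖₁ subject to
   * monotonicity: W·Eᵢ ≤ W·Eᵢ₊₁ for consecutive path points (the basin's
     energy ordering — its shape — is preserved),
   * smoothing: W·Eₙ ≤ (1/m) Σⱼ W·Eₙ⁽ʲ⁾ (the edge point drops below its
     neighborhood mean, so it stops being a ridge point),
   * W ≥ 0 and Σₖ wₖ = Σₖ w₀ₖ (no trivial rescaling).

Iteration stops when the Manhattan distance between successive weight
vectors falls below τ = 0.3, the published stopping rule.

## Realization choices

**L1 objective.**  ‖W − W₀‖ is realized as the L1 norm via auxiliary
variables u ≥ |w − w₀|, keeping the program linear; the weight budget
|W| = |W₀| is likewise the L1 norm, which equals the plain sum under
W ≥ 0.  Solved with HiGHS (`scipy.optimize.linprog`).

**Infeasibility.**  Some edge points genuinely cannot be smoothened by any
reweighting (every term of Eₙ can exceed the neighborhood mean).  Each
inequality row therefore carries a nonnegative slack penalized at 10⁴ in
the objective; a solution using slack is reported as `optimal_with_slack`,
never silently accepted as clean, and `verify_solution` re-checks every
row with plain numpy, independent of the solver.  All inequalities are
non-strict with zero margin; an optional epsilon margin exists for
strictness experiments but defaults to 0.

**Smoothing target.**  The default smoothing row compares the edge point
with the *mean* neighbor term vector.  A weaker variant
(`smoothing="hardest"`) compares it with the single neighbor of highest
energy under the anchor weights, so that at least one neighbor ends up
above the edge point; the disjunction "below at least one neighbor" is not
itself linear, and this is its tightest linear single-row surrogate.

**Constraint pooling across iterations.**  Each iteration draws
`paths_per_lp = 10` fresh reverse paths, but the LP keeps the constraint
rows of *all* paths drawn so far (`pool_iterations = True`).  With
per-iteration-only constraints the tuned weights oscillate: a direction
smoothened at iteration t can be re-flattened at t+1, and on a small term
set the optimizer can park all weight on a single integer-valued counting
term whose landscape is exactly flat along the sampled paths (zero-margin
rows tolerate ties), collapsing the basin radius.  Pooling makes the
feasible set shrink monotonically, so successive weight changes decrease —
the behavior the convergence rule presumes.  On the 16-residue helix
fixture, per-iteration LPs broaden the basin after three iterations in 1
of 5 replicates; pooled constraints with fine path sampling do so in 9 of
10 (the collapse remains possible but rare).

**Path subsampling.**  The monotonicity constraints nominally cover every
consecutive pair; `max_points = 60` caps the pairs kept per path (uniform
index spacing, endpoints always kept) purely to bound LP size.  Coarser
caps (e.g. 20) were observed to re-admit the flat-direction degeneracy
above, so the default errs toward fidelity.

**Anchoring.**  Each iteration's LP is anchored at that iteration's
current weights (W₀ = W_t), so the objective measures the incremental
change, matching the published trajectory in which successive schemes grow
similar while the final scheme is far from the initial one.

## The toy model

The original BARS protocol runs on Rosetta's 13-term score3; reimplementing
those terms is out of scope here.  The package instead ships a coarse-grained
Cα model whose energy has the same weighted-sum interface:

* **Geometry.**  Cα-only chain, virtual bonds fixed at 3.8 Å, N−2 pseudo
  bond angles in (0°, 180°) and N−3 pseudo torsions in (−180°, 180°];
  Cartesian coordinates via the natural-extension (NeRF) construction.
  Bond angles are clamped at the open-interval bounds, torsions wrap.
* **Terms** (K = 6, mirroring score3 roles): `clash` (soft steric overlap
  below 4 Å for |i−j| ≥ 3), `rg` (squared deviation of the radius of
  gyration from the Flory-like target 2.2·N^0.38 Å), `ss_local` (squared
  deviation of angles/torsions from secondary-structure ideals H: (89°,
  50°), E: (120°, −170°), scaled by 1/1000; coil free), `contact` (minus
  the count of native attraction pairs within 8 Å), `hbond` (squared
  deviation of helical i,i+4 distances from 6.2 Å, capped at 25), `env`
  (burial deficit of hydrophobic residues below 4 sequence-distant
  neighbors within 10 Å).  Torsion deviations use the wrapped (minimal)
  angular difference.
* **Move set.**  Fragment replacement is modeled as a Gaussian window
  move: a random contiguous window (default 3 residues) of torsions and
  bond angles perturbed with sd 10°.  One seeded generator per run, passed
  explicitly; the driver loop fans a master seed into per-(iteration,
  purpose, path) child streams, so runs are reproducible and paths
  order-independent.

**Monte Carlo defaults.**  Forward search uses Metropolis acceptance at
temperature 2.0 (energy units of the toy terms).  Reverse sampling stops
at `max_fail = 200` consecutive rejections or `max_steps = 500` accepted
points, whichever comes first; on the 16-residue fixtures ridges are
reached after roughly 60–120 accepted steps, so the failure budget is the
binding criterion, and paths record why they stopped.

## Synthetic natives

`bars.fixtures.make_native` emulates the role of a crystal-structure
native: a conformation that is a deep local minimum of the initial energy.
Three fold classes stand in for the benchmark set's SCOP classes: an
ideal α-helix, a β-hairpin (two strands, optimized turn), and a mixed
helix+strand fold.  Construction: build SS-ideal internal coordinates,
shape the coil region by a deterministic derivative-free optimization
(hairpin: cross-strand pair distances toward 5 Å; mixed: compactness),
read the topology off the geometry (attraction pairs at < 7 Å with 1 Å
margin to the contact cutoff; hydrophobic labels for residues with ≥ 5
distant neighbors, one above the burial floor), relax all internal
coordinates under uniform weights (L-BFGS-B, then a simplex polish across
the counting-term plateaus), and verify by brute force that 500 window-3 /
10° moves never go below the native energy.  A failed verification
restarts relaxation from the lowest offending conformation (a descent, so
the procedure terminates); everything is deterministic given the spec.

What the generator does *not* emulate: real side-chain packing, sequence-
specific term landscapes, the ruggedness of fragment-assembly moves, or
decoy ensembles from a production predictor.  Passing tests show the
machinery (reverse sampling, LP, loop) behaves as designed on a landscape
with honestly analogous structure — not that the tuned toy weights carry
over to real proteins.

## Scaled experiment sizes

The full published protocol (50 radius paths, m = 1000, 101 proteins,
Rosetta decoys) is replaced by desk-scale analogues chosen once: the
broadening experiment uses the 16-residue helix, 10 radius paths, m = 100,
3 tuning iterations and 5 independent replicates; decoy sets for the
good-decoy ratio use 40 forward searches from strongly distorted starts.
The published weight tables for 1ctfA/1iloA/1iieA ship as data and their
printed summary arithmetic (Manhattan distances, cosines) is recomputed
exactly; where a printed caption value is inconsistent with the printed
table columns (one adjacent distance, and the pairing order of the final
cosines), the recomputation-consistent values are used.

## Known limitations

* Six terms are few; the LP can still drive individual weights to zero,
  and some edge points are unsmoothable (handled via flagged slack).
* The basin radius under a tuned weighting is measured with the same move
  set and budgets as sampling; it is a relative, not absolute, measure.
* `select_prediction` uses greedy neighbor-count clustering with a 4 Å
  cutoff (the conventional centroid-of-largest-cluster reading); the
  embedding interprets "PCA of an RMSD matrix" as classical (Torgerson)
  multidimensional scaling, with raw-matrix PCA behind a flag.
* Reverse sampling is strict greedy uphill; stochastic acceptance of
  downhill moves is deliberately excluded so path monotonicity holds
  exactly.
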
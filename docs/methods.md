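# Methods

This note documents the model, the numerical choices and the known
limitations of `crnstab`, in the order the pipeline runs.

## Model and assumptions

Networks are finite sets of mass-action reaction steps between
*complexes* (nonnegative-integer combinations of species).  Throughout,
`m` = species, `n` = complexes, `l` = linkage classes, `s` = dimension
of the stoichiometric subspace, `delta = n - l - s` = deficiency.
Standing assumptions inherited from the theory:

* rate constants are strictly positive; kinetics are mass action;
* every linkage class has exactly one terminal strong linkage class
  (weak reversibility is the common special case) — this guarantees a
  one-dimensional, strictly positive kernel per block of the kinetic
  matrix, which the manifold construction requires and verifies;
* the molecularity matrix `Y` has full row rank `m`, and `m`
  independent complexes can be chosen with at least one per linkage
  class (checked; violation raises an unsupported-network error);
* only interior (strictly positive) equilibria are treated.  Boundary
  equilibria with zero concentrations are outside the theory and the
  implementation actively guards against certifying them (see below).

## Conventions that fix all downstream indexing

* **Canonical complex order**: ascending total molecularity, ties
  broken by descending coefficient tuple with species in declaration
  order.  For the Edelstein network this gives (A, B, C, 2A, A+B).
* **Conservation basis `B`**: mutually orthogonal columns of the
  orthogonal complement of the stoichiometric subspace, each scaled so
  its largest-magnitude entry is exactly +1 (Edelstein: `(0, 1, 1)^T`,
  so the conserved total reads `c_B + c_C` directly).
* **Deficiency basis `omega`**: mutually orthogonal null-space vectors
  of the stacked `[Y; class indicators]` matrix, max-entry-normalized
  with positive leading sign (Edelstein: `(1, -1, 0, -1, 1)`).  Any
  rescaling only reparametrizes `alpha`; the zero set of `det G` is
  unaffected, but the printed `det G` values are specific to this
  gauge.
* **Reference complexes**: one per linkage class, chosen by a
  coverage-first greedy rank selection in complex-index order; kernel
  vectors `rho` are normalized to 1 at the reference entry, making the
  eliminated kernel coefficients direct complex-space coordinates.
* **`eta` gauge**: the library stores the minimum-norm solution of
  `A_k eta_j = omega_j` (orthogonal to `ker A_k`); the interval
  evaluator uses the reference-entry-zero gauge instead because it
  makes `eta` a rational function amenable to interval linear solves.
  Kernel-direction shifts of `eta` cancel identically in `H`, `J_c`
  and `J_alpha`, so the two paths evaluate the same functions — a
  property the test suite asserts directly.

## Numerical choices

* **Rank decisions**: SVD with relative threshold `1e-10` times the
  largest singular value.  The matrices involved are small and
  integer-structured, far from ambiguous regimes.
* **Newton refinement** (`newton_refine`): damped (step-halving)
  least-squares Newton on `H`, convergence `||H|| <= 1e-12 (1+||c||)`,
  at most 50 iterations, with two safeguards: no component of `c` may
  lose more than 90 % per step, and since `H` is affine in `alpha`
  with a constant coefficient matrix, `alpha` is initialized at its
  least-squares optimum for the starting `c`.  Cold random starts
  still converge only for a fraction of seeds (a degenerate boundary
  attractor at vanishing concentrations stalls the rest); all
  operations that need manifold points therefore use seeded
  multi-start grids, following the branch-discovery design (default
  seed 20120703, log-uniform starts).
* **Certificates** (`multistationarity_certificate`): Newton on the
  square system `[H; det G] = 0`, determinant derivative by central
  finite differences with step `1e-6 (1+|x|)`.  Success requires
  `c > 0`, `||H|| <= 1e-8 (1+||c||)`, the scale-aware rank test
  `|det G| <= 1e-9 * (product of row norms)`, `min|alpha_j| >= 1e-9`
  (the complex-balanced branch `alpha = 0` is excluded — uniqueness
  holds there), and full row rank of `[J_c J_alpha]`
  (`sv_min > 1e-8 sv_max`).  The last condition is the smoothness
  hypothesis of the underlying propositions; without it, Newton runs
  on deficiency-zero fixtures can stall at near-boundary points where
  the whole matrix degenerates and the scale-relative determinant test
  passes vacuously.  Networks with `delta = 0` return no certificate
  by construction: they have no deficiency directions, so the
  `alpha != 0` hypothesis is unsatisfiable.
* **Uniqueness over a box** (`prove_unique_over_box`): two sound
  checks — the interval enclosure of `det G` over the box excludes
  zero, or the branch-and-prune enclosure of `{H = 0 and det G = 0}`
  restricted to the box is empty.  The second is needed in practice:
  `det G` routinely changes sign *off* the manifold, where its zeros
  are irrelevant to uniqueness.
* **Interval arithmetic**: closed intervals over ordinary doubles;
  every elementary operation widens its result outward by 4 ulps per
  endpoint (configurable), a conservative stand-in for directed
  rounding.  Even powers of zero-crossing intervals keep the exact
  zero lower bound.  Determinants by interval cofactor expansion up to
  size 5, interval LU with mignitude pivoting above; a pivot
  containing zero degrades the enclosure to the whole real line
  (soundness preserved, pruning power lost).
* **Branch-and-prune** (`solve_csp`): deterministic depth-first SIVIA.
  A box is discarded when any equality enclosure excludes zero or the
  domain constraints (`c > 0`, `|alpha| >= eps_alpha`) fail on all of
  it; accepted when its maximal relative width (width over
  `max(1, magnitude)`) is at most `eps`; otherwise bisected at the
  widest relative dimension (ties: lowest variable index).  No
  contractor propagation (HC4-style pruning) is applied — this is an
  efficiency feature, not a correctness one, and plain
  evaluate-discard-bisect keeps the solver easy to audit.  If the box
  budget is exhausted, all unprocessed boxes are returned as part of
  the paving and the result is flagged non-exhaustive; the outer
  enclosure property holds either way.  Because the solution set is a
  measure-zero variety (equality constraints), only the outer paving
  is meaningful; the inner paving is empty by construction.
* **Continuation** (`trace_curve`): natural-parameter continuation in
  a chosen species coordinate (default: the species with the largest
  `Y0` pivot), Newton-correcting the remaining `(c, alpha)` against
  the square pinned system; adaptive step halving on failure.  Only
  manifolds of dimension `m - s = 1` are supported; higher-dimensional
  manifolds should be explored with the interval search.  Folds are
  refined by bisection of `det G` along the curve to
  `|det G| <= 1e-9 * scale`; equilibria per compatibility class are
  crossings of `Gamma(t) = Gamma*` (bracketed bisection, or raw sample
  counting with `refine=False` for cheap sweeps).

## The Edelstein reference fixture

The bundled fixture uses species (A, B, C), complexes
(A, B, C, 2A, A+B) and reversible steps `A <-> 2A`, `B <-> C`,
`C <-> A+B` with constants (8.5, 1, 0.2, 1, 1, 1) in that step order.
The assignment of the six published constants to the six steps is
ambiguous in secondary sources; the default places 0.2 on `B -> C`,
the placement class that yields the three-equilibria/two-fold regime,
and every placement within that class produces the identical
equilibrium set in `(c_A, Gamma)`.  The constructor accepts an
explicit rate tuple for users with the original assignment.  A variant
with 0.2 moved to `A + B -> C` is the bundled negative control: its
`Gamma(A)` is monotone on the positive branch and no folds exist.

## What the random generator emulates — and what it does not

`random_weakly_reversible` samples distinct complexes with
molecularities 0–2 per species, partitions them into linkage classes
of at least two complexes, joins each class by a random spanning tree
of *reversible* edges (plus optional extras) and draws rate constants
log-uniformly (default one decade around 1).  Weak reversibility holds
by construction and generation is byte-deterministic per seed.  These
fixtures exercise the structural identities (`delta = n - l - s >= 0`,
conservation orthogonality, kernel positivity, matrix-tree equality)
across many topologies.  They are *not* biologically calibrated: real
signalling networks have conserved enzyme totals, sparse stoichiometry
and rate constants spanning many decades.  Passing tests demonstrate
correctness of the algebra and the reliability contract of the
enclosures, not coverage of any particular biological parameter
regime.  The deficiency-zero screen draws from this generator by
rejection (keeping `delta = 0` networks), which biases it toward small
tree-like classes — exactly the regime where the deficiency-zero
theorem applies and the screen must never produce a certificate.

## Problem sizes used by the shipped analyses

The bundled analyses run the Edelstein curve at step 0.02 over
`c_A ∈ [0.25, 8.4]` (~400 samples), sweep `Gamma` over `[20, 40]` in
steps of 0.05, search the CSP over `[1e-3, 50]^3 × [-60, -1e-3]` at
`eps ∈ {0.2, 0.1, 0.05, 0.02}` (about 32 000 boxes processed at the
finest setting), screen 100 random deficiency-zero networks and check
500 nested-box inclusion pairs.  These sizes resolve all reported
quantities to well beyond their stated tolerances.

## Known limitations

* No interval-Newton existence test inside boxes: the paving encloses
  all solutions but does not prove a solution exists in any given box.
* No contractor-based pruning; high-dimensional searches (many free
  rate constants) will bisect heavily.  The matrix-tree interval
  evaluation of `rho` is limited to linkage classes of at most 8
  complexes.
* Continuation handles 1-D manifolds only, and stability of equilibria
  (eigenvalue classification) is not computed anywhere.
* Interval soundness relies on the ulp-widening model; it is
  conservative for every elementary operation on finite doubles but
  has no formal proof against compiler re-association, unlike a true
  directed-rounding library.
* SBML input, non-mass-action kinetics and time-varying inflows are
  out of scope.
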
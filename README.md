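# crnstab

Characterizing multistationarity regimes of mass-action biochemical
reaction networks: structural Chemical Reaction Network Theory (CRNT)
analysis, a canonical construction of the equilibrium manifold, a
rank-deficiency condition certifying multiple steady states, and a
reliable interval branch-and-prune search that returns guaranteed outer
enclosures of the multistationary regions of (state-)parameter space.

## Who this is for

Bistable switches are a central motif in systems and synthetic biology
(cell-fate decisions, toggle circuits, autocatalytic cycles).  Deciding
whether a given mass-action network *can* have multiple positive steady
states — and for which rate constants and conserved totals it actually
does — is the problem this package addresses.  It is aimed at modellers
who have a reaction mechanism (species, reaction arrows, rate
constants) and want structural verdicts, bifurcation information and
certified parameter regions without hand-deriving steady-state algebra.

## The method

For a network with `m` species, `n` complexes, `l` linkage classes and
rate constants `K`, the dynamics are `dc/dt = Y A_k Psi(c)` with `Y`
the molecularity matrix, `A_k` the (Laplacian-like) kinetic matrix and
`Psi_p(c) = prod_k c_k^{y_kp}` the mass-action monomials.

* **Structure.**  Linkage classes, weak reversibility, the
  stoichiometric subspace `S` (dimension `s`), the conservation basis
  `B` (`B^T c` is constant on trajectories) and the deficiency
  `delta = n - l - s`.  Weakly reversible networks with `delta = 0`
  have a unique stable positive equilibrium per stoichiometric
  compatibility class, so multistationarity is excluded structurally.
* **Equilibrium manifold.**  All positive equilibria satisfy
  `A_k Psi(c) = sum_j alpha_j omega_j` with `omega_1..omega_delta` a
  basis of the deficiency subspace `D = ker Y  ∩  {per-class sums = 0}`.
  Writing `Psi = sum_i lambda_i rho_i + sum_j alpha_j eta_j` (with
  `rho_i` the positive kernel vectors of `A_k`, one per linkage class,
  and `A_k eta_j = omega_j`) and eliminating `lambda` against one
  reference complex per class yields `s + delta` residual equations
  `H(c, alpha) = 0` — the manifold, of dimension `m - s`.
* **Multistationarity condition.**  Stack the Jacobians of `H` with the
  conservation rows into the square `(m + delta)` matrix
  `G = [[J_c, J_alpha], [B^T, 0]]`.  Full rank of `G` along the
  manifold implies at most one equilibrium per compatibility class;
  `det G = 0` at a manifold point with `alpha != 0` is a sufficient
  condition for multiple positive equilibria.  Zeros of `det G` along a
  1-D equilibrium curve are exactly its saddle-node (fold) points.
* **Interval search.**  The condition is posed as a constraint
  satisfaction problem — `H = 0`, `det G = 0`, `c > 0`,
  `|alpha| >= eps_alpha` — over any chosen free variables (rate
  constants, concentrations, `alpha`) and solved by a deterministic
  SIVIA-style branch-and-prune with outward-rounded interval
  arithmetic.  The returned subpaving is a *guaranteed outer
  enclosure*: every true solution in the search box lies in the union
  of returned boxes.

## Worked example

The Edelstein autocatalytic network — `A <-> 2A`, `B <-> C`,
`C <-> A+B` with rate constants (8.5, 1, 0.2, 1, 1, 1) — is the
bundled reference case:

```sh
$ crnstab fixtures edelstein --out edelstein.crn
$ crnstab analyze edelstein.crn
species: A, B, C (m=3)
complexes: n=5
linkage classes: l=2
stoichiometric subspace: s=2
deficiency: 1  (proper layout, manifold dimension 1)
weakly reversible: True
multistationarity not excluded
```

Tracing the equilibrium curve in `c_A` and detecting folds:

```sh
$ crnstab continue edelstein.crn --param A --range 0.25 8.4 --step 0.05 --out curve.csv
curve: 165 samples, 2 fold(s)
  fold at A = 1.2528, Gamma = 29.7768
  fold at A = 2.74164, Gamma = 30.6949
```

The two folds bound the bistable window of the conserved total
`Gamma = c_B + c_C`: for `Gamma` between 29.78 and 30.70 the network
has three positive equilibria in one compatibility class (e.g. at
`Gamma = 30`: `c_A ∈ {1.0000, 1.6388, 3.6612}`), and one outside.  The
same two points are where `det G` vanishes along the curve; from the
library:

```python
>>> import numpy as np
>>> from crnstab import fixtures, build_manifold, g_matrix
>>> net, K = fixtures.edelstein()
>>> model = build_manifold(net, K)
>>> g_matrix(model, np.array([1.0, 18.75, 11.25]), np.array([-7.5])).det
-1.6999999999999937
```

(`det G < 0` between the folds, `> 0` outside — the sign change is the
fold.)  The interval search encloses the rank-deficient equilibria in
a guaranteed paving:

```sh
$ crnstab search edelstein.crn --config search.toml --out paving.json
paving: 1346 boxes, volume 0.320354, exhaustive=True
```

with `search.toml` freeing `A`, `B`, `C` in `[1e-3, 50]` and `alpha`
in `[-60, -1e-3]` at `eps = 0.02`; both fold points lie inside the
returned boxes.

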
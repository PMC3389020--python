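"""Canonical construction of the equilibrium manifold.

For a mass-action network the positive equilibria split into the
complex-balanced branch (``A_k Psi(c) = 0``) and, when the deficiency
``delta > 0``, a wider branch where ``A_k Psi(c)`` is a nonzero element
of the deficiency subspace ``D = ker Y  ∩  {per-class sums zero}``.
Parametrizing that element by ``alpha in R^delta`` and eliminating the
per-linkage-class kernel coefficients against one *reference complex*
per class yields ``n - l = s + delta`` residual equations
``H(c, alpha) = 0`` whose positive solution set is the full equilibrium
manifold (dimension ``m - s``).

The ingredients, all computed here:

* kinetic matrix ``A_k`` (block Laplacian-like, one block per linkage class),
* kernel basis ``rho`` of ``A_k`` (one strictly positive vector per class,
  cross-checkable against the matrix-tree spanning-tree expansion),
* deficiency-subspace basis ``omega`` and particular solutions ``eta`` of
  ``A_k eta_j = omega_j``,
* reference complexes / ``Y0`` / the exponent matrix ``Yhat`` of the
  mass-action manifold, and the species<->complex-space bijection ``phi``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .network import (
    NetworkError,
    ReactionNetwork,
    StructuralReport,
    structural_report,
)

__all__ = [
    "kinetic_matrix",
    "psi",
    "species_rhs",
    "rho_matrix_tree",
    "spanning_in_trees",
    "ManifoldModel",
    "build_manifold",
    "deficiency_basis",
    "select_reference_complexes",
    "manifold_equations",
    "manifold_jacobian",
    "phi_map",
    "phi_inverse",
    "newton_refine",
    "model_to_json",
]

ETA_RESIDUAL_RTOL = 1e-10
KERNEL_RTOL = 1e-12


# ---------------------------------------------------------------------------
# Mass-action dynamics
# ---------------------------------------------------------------------------

def kinetic_matrix(net: ReactionNetwork, K: np.ndarray) -> np.ndarray:
    """n x n kinetic matrix: ``A_k[j, i] = k_{i->j}``, zero column sums.

    Block structure follows the linkage classes (no coupling between
    classes); the species dynamics are ``dc/dt = Y A_k Psi(c)``.
    """
    K = np.asarray(K, dtype=float)
    if K.shape != (net.n_reactions,):
        raise NetworkError(
            f"expected {net.n_reactions} rate constants, got {K.shape}")
    if np.any(K <= 0):
        raise NetworkError("rate constants must be strictly positive")
    n = net.n_complexes
    A = np.zeros((n, n))
    for (i, j, _), k in zip(net.reactions, K):
        A[j, i] += k
        A[i, i] -= k
    return A


def psi(net: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """Mass-action monomial vector ``Psi_p(c) = prod_k c_k^{y_kp}``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    Y = net.Y
    return np.prod(c[:, None] ** Y, axis=0)


def species_rhs(net: ReactionNetwork, K: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Species formation rate ``dc/dt = Y A_k Psi(c)``."""
    return net.Y @ kinetic_matrix(net, K) @ psi(net, c)


# ---------------------------------------------------------------------------
# Kernel basis: numeric null space and matrix-tree expansion
# ---------------------------------------------------------------------------

def spanning_in_trees(
    nodes: tuple[int, ...],
    edges: list[tuple[int, int, int]],
    root: int,
) -> list[tuple[int, ...]]:
    """All spanning in-trees of a linkage-class digraph, rooted at ``root``.

    ``edges`` are ``(src, tgt, reaction_index)`` within the class.  An
    in-tree assigns every non-root node exactly one outgoing edge such
    that all paths lead to the root.  Returns tuples of reaction indices
    (one per tree).  Exponential enumeration, intended for classes of up
    to ~8 complexes where it doubles as an independent oracle.
    """
    out_edges: dict[int, list[tuple[int, int]]] = {v: [] for v in nodes if v != root}
    for src, tgt, ridx in edges:
        if src != root:
            out_edges[src].append((tgt, ridx))
    non_root = [v for v in nodes if v != root]
    if any(not out_edges[v] for v in non_root):
        return []
    trees = []
    for choice in itertools.product(*(out_edges[v] for v in non_root)):
        succ = {v: tgt for v, (tgt, _) in zip(non_root, choice)}
        ok = True
        for v in non_root:
            seen = set()
            u = v
            while u != root:
                if u in seen:
                    ok = False
                    break
                seen.add(u)
                u = succ[u]
            if not ok:
                break
        if ok:
            trees.append(tuple(ridx for _, ridx in choice))
    return trees


def rho_matrix_tree(
    net: ReactionNetwork,
    K: np.ndarray,
    linkage_class: tuple[int, ...],
) -> dict[int, float]:
    """Kernel entries of the class block by the matrix-tree theorem.

    ``rho_i`` is the sum over spanning in-trees rooted at complex ``i``
    of the product of the tree's rate constants.  Serves as the
    independent cross-check of the SVD null-space computation and as the
    closed-form used when rate constants are interval-valued.
    """
    if len(linkage_class) > 8:
        raise NetworkError("matrix-tree expansion limited to classes with <= 8 complexes")
    members = set(linkage_class)
    edges = [(i, j, r) for r, (i, j, _) in enumerate(net.reactions) if i in members]
    K = np.asarray(K, dtype=float)
    rho = {}
    for root in linkage_class:
        trees = spanning_in_trees(linkage_class, edges, root)
        rho[root] = float(sum(np.prod(K[list(t)]) if t else 1.0 for t in trees))
    return rho


# ---------------------------------------------------------------------------
# Deficiency subspace and reference complexes
# ---------------------------------------------------------------------------

def _normalize_columns(M: np.ndarray) -> np.ndarray:
    """Scale each column so its largest-magnitude entry is exactly +1."""
    M = M.copy()
    for j in range(M.shape[1]):
        col = M[:, j]
        mags = np.abs(col)
        lead = int(np.flatnonzero(mags >= mags.max() * (1 - 1e-12))[0])
        M[:, j] = col / col[lead]
    return M


def deficiency_basis(report: StructuralReport) -> np.ndarray:
    """Basis of the deficiency subspace ``D``, as an n x delta matrix.

    ``D = { d : Y d = 0  and  (per-linkage-class sums of d) = 0 }``,
    computed as the SVD null space of the stacked (m + l) x n matrix of
    ``Y`` over the class indicator rows.  Columns are mutually
    orthogonal and scaled so the largest-magnitude entry of each is +1
    (a deterministic convention; any rescaling only reparametrizes the
    deficiency parameters alpha).
    """
    stacked = np.vstack([report.Y, report.omega_indicators])
    U, sv, Vt = np.linalg.svd(stacked)
    tol = 1e-10 * (sv[0] if sv.size else 1.0)
    rank = int(np.sum(sv > tol))
    null = Vt[rank:].T                      # n x delta, orthonormal
    if null.shape[1] != report.deficiency:
        raise NetworkError(
            f"deficiency-subspace dimension {null.shape[1]} != delta "
            f"{report.deficiency}")
    if null.shape[1] == 0:
        return null
    return _normalize_columns(null)


def select_reference_complexes(
    report: StructuralReport,
) -> tuple[tuple[int, ...], np.ndarray, np.ndarray, tuple[int, ...]]:
    """Choose ``m`` complexes with independent molecularity vectors.

    The selection is greedy in complex-index order but first guarantees
    one complex per linkage class (coverage pass), then fills up to
    rank ``m``.  The per-class complex chosen in the coverage pass is
    the class's lambda-elimination reference.

    Returns ``(selected, Y0, Yhat, refs)`` where ``Y0`` collects the
    selected molecularity columns, ``Yhat = Y^T Y0^{-T}`` and ``refs``
    holds one reference complex index per linkage class.
    """
    Y = report.Y
    m = Y.shape[0]
    if np.linalg.matrix_rank(Y, tol=1e-10 * max(1.0, np.abs(Y).max())) < m:
        raise NetworkError(
            "molecularity matrix is rank deficient (rank Y < m); this "
            "network falls outside the supported class")
    selected: list[int] = []
    refs: list[int] = []

    def rank_of(cols: list[int]) -> int:
        return int(np.linalg.matrix_rank(Y[:, cols])) if cols else 0

    for cls in report.linkage_classes:
        chosen = None
        for i in cls:
            if rank_of(selected + [i]) > rank_of(selected):
                chosen = i
                break
        if chosen is None:
            raise NetworkError(
                "cannot place an independent reference complex in every "
                "linkage class; this network falls outside the supported class")
        selected.append(chosen)
        refs.append(chosen)
    for i in range(report.net.n_complexes):
        if len(selected) == m:
            break
        if i in selected:
            continue
        if rank_of(selected + [i]) > rank_of(selected):
            selected.append(i)
    if len(selected) < m:
        raise NetworkError("failed to select m independent complexes")
    selected_sorted = tuple(sorted(selected))
    Y0 = Y[:, selected_sorted]
    Yhat = Y.T @ np.linalg.inv(Y0.T)
    return selected_sorted, Y0, Yhat, tuple(refs)


# ---------------------------------------------------------------------------
# The manifold model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifoldModel:
    """Everything needed to evaluate the manifold residual ``H(c, alpha)``.

    ``rho`` is the full-length kernel vector (positive exactly on each
    linkage class, reference entries equal to 1), ``omega`` the n x delta
    deficiency basis, ``eta`` the n x delta minimum-norm solutions of
    ``A_k eta_j = omega_j`` and ``nonref`` the ``n - l = s + delta``
    non-reference complexes, in complex order, that carry one residual
    component each.
    """

    net: ReactionNetwork
    report: StructuralReport
    K: np.ndarray
    A_k: np.ndarray
    rho: np.ndarray
    omega: np.ndarray
    eta: np.ndarray
    selected: tuple[int, ...]
    Y0: np.ndarray
    Yhat: np.ndarray
    ref_complexes: tuple[int, ...]       # one per linkage class
    class_of: tuple[int, ...]            # complex index -> linkage class index
    nonref: tuple[int, ...]

    @property
    def alpha_dim(self) -> int:
        return self.omega.shape[1]

    def ref_of(self, p: int) -> int:
        return self.ref_complexes[self.class_of[p]]


def build_manifold(
    net: ReactionNetwork,
    K: np.ndarray,
    report: StructuralReport | None = None,
) -> ManifoldModel:
    """Construct the canonical manifold model for a rate-constant vector.

    Requires every linkage class to have exactly one terminal strong
    class (weak reversibility is the common special case); otherwise the
    kernel of the kinetic matrix is too small and the construction is
    refused.
    """
    if report is None:
        report = structural_report(net)
    if not report.single_terminal_per_class:
        raise NetworkError(
            "manifold construction needs exactly one terminal strong class "
            "per linkage class")
    K = np.asarray(K, dtype=float)
    A = kinetic_matrix(net, K)
    selected, Y0, Yhat, refs = select_reference_complexes(report)

    class_of = [0] * net.n_complexes
    for ci, cls in enumerate(report.linkage_classes):
        for p in cls:
            class_of[p] = ci

    # kernel vector per class, normalized so rho[ref] = 1
    n = net.n_complexes
    rho = np.zeros(n)
    for ci, cls in enumerate(report.linkage_classes):
        idx = list(cls)
        block = A[np.ix_(idx, idx)]
        _, sv, Vt = np.linalg.svd(block)
        small = sv <= 1e-10 * max(sv[0], 1.0)
        if int(np.sum(small)) != 1:
            raise NetworkError(
                "kinetic-matrix block kernel is not one-dimensional")
        v = Vt[-1]
        v = v / v[idx.index(refs[ci])]
        if np.any(v <= 0):
            raise NetworkError("kernel vector not strictly positive on its class")
        rho[idx] = v

    omega = deficiency_basis(report)
    if omega.shape[1]:
        eta, *_ = np.linalg.lstsq(A, omega, rcond=None)
        resid = np.linalg.norm(A @ eta - omega, axis=0)
        if np.any(resid > ETA_RESIDUAL_RTOL * np.maximum(
                np.linalg.norm(omega, axis=0), 1.0)):
            raise NetworkError(
                "omega not in range of kinetic matrix (network is not "
                "weakly reversible enough for the manifold construction)")
    else:
        eta = np.zeros((n, 0))

    nonref = tuple(p for p in range(n) if p not in refs)
    return ManifoldModel(
        net=net, report=report, K=K, A_k=A, rho=rho, omega=omega, eta=eta,
        selected=selected, Y0=Y0, Yhat=Yhat, ref_complexes=refs,
        class_of=tuple(class_of), nonref=nonref,
    )


# ---------------------------------------------------------------------------
# Residual equations, Jacobians, bijection
# ---------------------------------------------------------------------------

def manifold_equations(
    model: ManifoldModel, c: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Residuals ``H(c, alpha)``: ``s + delta`` components, one per
    non-reference complex ``p`` with class reference ``r``::

        H_p = Psi_p - (rho_p / rho_r) (Psi_r - sum_j alpha_j eta_jr)
                    - sum_j alpha_j eta_jp

    ``H(c, alpha) = 0`` for some ``alpha`` iff ``c`` is a positive
    equilibrium; ``alpha = 0`` recovers the complex-balanced branch.
    """
    c = np.asarray(c, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    if alpha.shape != (model.alpha_dim,):
        raise ValueError(f"alpha must have length {model.alpha_dim}")
    P = psi(model.net, c)
    ea = model.eta @ alpha                   # length n
    H = np.empty(len(model.nonref))
    for row, p in enumerate(model.nonref):
        r = model.ref_of(p)
        H[row] = P[p] - model.rho[p] / model.rho[r] * (P[r] - ea[r]) - ea[p]
    return H


def manifold_jacobian(
    model: ManifoldModel, c: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobians ``(J_c, J_alpha)`` of ``H`` at ``(c, alpha)``."""
    c = np.asarray(c, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    Y = model.net.Y
    P = psi(model.net, c)
    rows = len(model.nonref)
    Jc = np.zeros((rows, model.net.n_species))
    Ja = np.zeros((rows, model.alpha_dim))
    for row, p in enumerate(model.nonref):
        r = model.ref_of(p)
        ratio = model.rho[p] / model.rho[r]
        Jc[row] = (Y[:, p] * P[p] - ratio * Y[:, r] * P[r]) / c
        Ja[row] = ratio * model.eta[r] - model.eta[p]
    return Jc, Ja


def phi_map(model: ManifoldModel, psi0: np.ndarray) -> np.ndarray:
    """Complex-space -> species-space bijection ``c = exp(Y0^-T ln psi0)``."""
    psi0 = np.asarray(psi0, dtype=float)
    if np.any(psi0 <= 0):
        raise ValueError("psi0 must be strictly positive")
    return np.exp(np.linalg.solve(model.Y0.T, np.log(psi0)))


def phi_inverse(model: ManifoldModel, c: np.ndarray) -> np.ndarray:
    """Inverse bijection ``psi0 = exp(Y0^T ln c)`` (the reference monomials)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("c must be strictly positive")
    return np.exp(model.Y0.T @ np.log(c))


# ---------------------------------------------------------------------------
# Newton refinement on the manifold
# ---------------------------------------------------------------------------

def newton_refine(
    model: ManifoldModel,
    c0: np.ndarray,
    alpha0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Damped (step-halving) Newton for ``H(c, alpha) = 0``.

    The system is underdetermined in general (``s + delta`` equations in
    ``m + delta`` unknowns); the least-squares Newton step converges to
    the nearest manifold point.  Positivity of ``c`` is enforced by the
    damping.  Returns ``(c, alpha, converged)`` with convergence when
    ``||H|| <= tol (1 + ||c||)``.

    ``H`` is affine in ``alpha`` with a constant coefficient matrix, so
    when ``alpha0`` is None the starting value is the least-squares
    optimum for ``c0`` — this makes convergence from rough ``c`` guesses
    far more reliable than a cold start.
    """
    c = np.array(c0, dtype=float)
    if alpha0 is None and model.alpha_dim:
        _, Ja = manifold_jacobian(model, c, np.zeros(model.alpha_dim))
        H0 = manifold_equations(model, c, np.zeros(model.alpha_dim))
        alpha0, *_ = np.linalg.lstsq(Ja, -H0, rcond=None)
    elif alpha0 is None:
        alpha0 = np.zeros(0)
    alpha = np.atleast_1d(np.array(alpha0, dtype=float))
    for _ in range(max_iter):
        H = manifold_equations(model, c, alpha)
        if np.linalg.norm(H) <= tol * (1.0 + np.linalg.norm(c)):
            return c, alpha, True
        Jc, Ja = manifold_jacobian(model, c, alpha)
        J = np.hstack([Jc, Ja])
        step, *_ = np.linalg.lstsq(J, -H, rcond=None)
        # positivity safeguard: no component of c may lose more than 90%
        # in one step (keeps iterates away from the degenerate boundary)
        dc = step[: len(c)]
        shrink = dc < 0
        t = 1.0
        if np.any(shrink):
            t = min(1.0, float(np.min(0.9 * c[shrink] / -dc[shrink])))
        base = np.linalg.norm(H)
        for _ in range(30):
            c_new = c + t * step[: len(c)]
            a_new = alpha + t * step[len(c):]
            if np.all(c_new > 0):
                if np.linalg.norm(
                        manifold_equations(model, c_new, a_new)) < base:
                    break
            t *= 0.5
        else:
            return c, alpha, False
        c, alpha = c_new, a_new
    H = manifold_equations(model, c, alpha)
    return c, alpha, bool(np.linalg.norm(H) <= tol * (1.0 + np.linalg.norm(c)))


def model_to_json(model: ManifoldModel) -> str:
    """Serialize the manifold model for reproducibility."""
    doc = {
        "species": list(model.net.species),
        "complexes": [list(y) for y in model.net.complexes],
        "reactions": [[i, j, k] for i, j, k in model.net.reactions],
        "K": model.K.tolist(),
        "rho": model.rho.tolist(),
        "omega": model.omega.tolist(),
        "eta": model.eta.tolist(),
        "selected_complexes": list(model.selected),
        "reference_complexes": list(model.ref_complexes),
        "Y0": model.Y0.tolist(),
        "Yhat": model.Yhat.tolist(),
        "deficiency": model.report.deficiency,
        "s": model.report.s,
    }
    return json.dumps(doc, indent=2)
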
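"""The rank-deficiency condition for multiple steady states.

Stacking the Jacobians of the manifold residuals ``H(c, alpha)`` over
``(c, alpha)`` with the conservation rows ``B^T`` gives the square
``(m + delta) x (m + delta)`` matrix::

    G = [[ J_c,  J_alpha ],
         [ B^T,  0       ]]

At a positive equilibrium (``H = 0``) with full-rank ``G`` the
equilibrium is locally the unique intersection of the manifold with its
stoichiometric compatibility class; rank deficiency of ``G`` at a
manifold point with nonzero ``alpha`` is a sufficient condition for the
network to admit multiple positive equilibria within one compatibility
class.  ``alpha = 0`` is excluded because it is the complex-balanced
branch, where uniqueness holds regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import Box, Interval, MultistatConstraints
from .manifold import (
    ManifoldModel,
    manifold_equations,
    manifold_jacobian,
    phi_map,
)

__all__ = [
    "GEvaluation",
    "Certificate",
    "g_matrix",
    "g_matrix_complex_space",
    "multistationarity_certificate",
    "prove_unique_over_box",
]

#: |det G| <= DET_RTOL * (product of row norms) declares rank deficiency
DET_RTOL = 1e-9

#: certificates require min_j |alpha_j| >= this (complex-balanced exclusion)
ALPHA_EXCLUSION = 1e-9


@dataclass(frozen=True)
class GEvaluation:
    """G matrix at a point, its determinant and the rank verdict."""

    G: np.ndarray
    det: float
    scale: float               # Hadamard bound: product of row norms
    rank_deficient: bool


@dataclass(frozen=True)
class Certificate:
    """Multistationarity certificate at a refined point.

    Existence of a point ``(c, alpha)`` with ``H = 0``, ``det G = 0``,
    ``c > 0`` and ``alpha`` bounded away from zero implies a
    stoichiometric compatibility class carrying at least two positive
    equilibria.
    """

    c: np.ndarray
    alpha: np.ndarray
    det: float
    h_norm: float
    gamma: np.ndarray          # conserved totals B^T c at the point


def _assemble_g(model: ManifoldModel, c, alpha) -> np.ndarray:
    Jc, Ja = manifold_jacobian(model, c, alpha)
    B = model.report.B
    top = np.hstack([Jc, Ja])
    bottom = np.hstack([B.T, np.zeros((B.shape[1], model.alpha_dim))])
    return np.vstack([top, bottom])


def g_matrix(
    model: ManifoldModel, c, alpha, det_rtol: float = DET_RTOL
) -> GEvaluation:
    """Evaluate G, its determinant (LU) and the scale-aware rank verdict.

    Rows are ordered (H components in complex order, conservation rows
    in B-column order), columns (species order, then alpha); only the
    zero set of the determinant carries meaning, the ordering is a
    convention.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    G = _assemble_g(model, c, alpha)
    det = float(np.linalg.det(G))
    row_norms = np.linalg.norm(G, axis=1)
    scale = float(np.prod(np.maximum(row_norms, 1e-300)))
    return GEvaluation(
        G=G, det=det, scale=scale, rank_deficient=abs(det) <= det_rtol * scale)


def g_matrix_complex_space(
    model: ManifoldModel, psi0, alpha, det_rtol: float = DET_RTOL
) -> GEvaluation:
    """The same condition expressed in the space of complexes.

    With ``c = phi(psi0)`` the chain rule gives
    ``J_phi = diag(c) Y0^-T diag(1/psi0)`` and::

        G' = [[ J_c J_phi,  J_alpha ],
              [ B^T J_phi,  0       ]]

    so ``det G' = det G * det J_phi`` — the zero sets coincide because
    ``J_phi`` is invertible for positive arguments.
    """
    psi0 = np.asarray(psi0, dtype=float)
    if np.any(psi0 <= 0):
        raise ValueError("psi0 must be strictly positive")
    c = phi_map(model, psi0)
    Jc, Ja = manifold_jacobian(model, c, alpha)
    J_phi = np.diag(c) @ np.linalg.inv(model.Y0.T) @ np.diag(1.0 / psi0)
    B = model.report.B
    top = np.hstack([Jc @ J_phi, Ja])
    bottom = np.hstack([B.T @ J_phi, np.zeros((B.shape[1], model.alpha_dim))])
    G = np.vstack([top, bottom])
    det = float(np.linalg.det(G))
    row_norms = np.linalg.norm(G, axis=1)
    scale = float(np.prod(np.maximum(row_norms, 1e-300)))
    return GEvaluation(
        G=G, det=det, scale=scale, rank_deficient=abs(det) <= det_rtol * scale)


def multistationarity_certificate(
    model: ManifoldModel,
    c0,
    alpha0,
    det_rtol: float = DET_RTOL,
    alpha_exclusion: float = ALPHA_EXCLUSION,
    max_iter: int = 60,
) -> Certificate | None:
    """Newton refinement of ``[H(c, alpha); det G(c, alpha)] = 0``.

    The determinant row's derivative is taken by central finite
    differences with step ``1e-6 (1 + |x|)`` per coordinate.  Success
    requires convergence to a strictly positive ``c`` with
    ``min_j |alpha_j| >= alpha_exclusion``; otherwise ``None``.

    Networks with zero deficiency have no deficiency directions at all:
    every positive equilibrium is complex balanced, the ``alpha != 0``
    hypothesis is unsatisfiable and no certificate can exist.
    """
    if model.alpha_dim == 0:
        return None
    c = np.array(c0, dtype=float)
    alpha = np.atleast_1d(np.array(alpha0, dtype=float))
    m = len(c)

    def residual(x):
        cc, aa = x[:m], x[m:]
        if np.any(cc <= 0):
            return None
        H = manifold_equations(model, cc, aa)
        det = float(np.linalg.det(_assemble_g(model, cc, aa)))
        return np.concatenate([H, [det]])

    x = np.concatenate([c, alpha])
    F = residual(x)
    if F is None:
        return None
    for _ in range(max_iter):
        cc, aa = x[:m], x[m:]
        Jc, Ja = manifold_jacobian(model, cc, aa)
        J_top = np.hstack([Jc, Ja])
        det_grad = np.empty(len(x))
        for i in range(len(x)):
            h = 1e-6 * (1.0 + abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fp, fm = residual(xp), residual(xm)
            if fp is None or fm is None:
                # fall back to one-sided difference at the positivity boundary
                f0 = residual(x)
                side = fp if fp is not None else fm
                sign = 1.0 if fp is not None else -1.0
                if side is None:
                    return None
                det_grad[i] = sign * (side[-1] - f0[-1]) / h
            else:
                det_grad[i] = (fp[-1] - fm[-1]) / (2 * h)
        J = np.vstack([J_top, det_grad])
        step, *_ = np.linalg.lstsq(J, -F, rcond=None)
        base = np.linalg.norm(F)
        t = 1.0
        improved = False
        for _ in range(30):
            x_new = x + t * step
            F_new = residual(x_new)
            if F_new is not None and np.linalg.norm(F_new) < base:
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        x, F = x_new, F_new
        if np.linalg.norm(F) <= 1e-12 * (1.0 + np.linalg.norm(x)):
            break

    cc, aa = x[:m], x[m:]
    if np.any(cc <= 0):
        return None
    H = manifold_equations(model, cc, aa)
    ev = g_matrix(model, cc, aa, det_rtol=det_rtol)
    h_ok = np.linalg.norm(H) <= 1e-8 * (1.0 + np.linalg.norm(cc))
    if not (h_ok and ev.rank_deficient):
        return None
    # the condition presumes a locally smooth manifold: the residual
    # Jacobian must be full row rank, otherwise the point is a
    # degenerate (typically near-boundary) parametrization artifact
    Jc, Ja = manifold_jacobian(model, cc, aa)
    sv = np.linalg.svd(np.hstack([Jc, Ja]), compute_uv=False)
    if sv[-1] <= 1e-8 * sv[0]:
        return None
    if aa.size and np.min(np.abs(aa)) < alpha_exclusion:
        return None
    return Certificate(
        c=cc, alpha=aa, det=ev.det, h_norm=float(np.linalg.norm(H)),
        gamma=model.report.B.T @ cc,
    )


def prove_unique_over_box(
    model: ManifoldModel,
    box: Box,
    fixed: dict[str, float] | None = None,
    eps: float = 0.02,
    max_boxes: int = 200_000,
) -> str:
    """Interval uniqueness proof over a whole ``(c, alpha)`` box.

    Two sound sufficient checks, in order:

    1. the interval enclosure of ``det G`` over the box excludes zero
       (no point of the box is rank deficient), or
    2. the branch-and-prune enclosure of ``{H = 0 and det G = 0}``
       restricted to the box comes back empty — no *manifold* point of
       the box is rank deficient, which is all the uniqueness statement
       needs (``det G`` may well vanish off the manifold).

    Either returns ``"proven"``; otherwise ``"unknown"`` (never
    "false": enclosure overshoot is indistinguishable from a true
    solution).
    """
    cons = MultistatConstraints(model)
    fixed = dict(fixed or {})
    env: dict[str, Interval] = {
        f"k{i + 1}": Interval(float(k), float(k))
        for i, k in enumerate(model.K)
    }
    for name, value in fixed.items():
        env[name] = Interval(value, value)
    env.update(zip(box.names, box.intervals))
    if not cons.det_g(env).contains_zero():
        return "proven"

    from .intervals import CSProblem, solve_csp

    k_fixed = {f"k{i + 1}": float(k) for i, k in enumerate(model.K)}
    problem = CSProblem(
        box=box,
        equalities=cons.constraints(include_det=True),
        fixed={**k_fixed, **fixed},
        eps=eps,
        eps_alpha=0.0,          # uniqueness needs emptiness on all of the box
        max_boxes=max_boxes,
    )
    paving = solve_csp(problem)
    if paving.exhaustive and not paving.boxes:
        return "proven"
    return "unknown"
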
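"""Tracing 1-D equilibrium curves, folds and equilibria per class.

For networks whose equilibrium manifold is one dimensional
(``m - s = 1``) the positive equilibria form a curve in ``(c, alpha)``
space.  Fixing one species coordinate and Newton-correcting the
remaining ``m - 1 + delta`` unknowns against the ``s + delta`` manifold
residuals walks the curve (natural-parameter continuation, with a
pseudo-arclength fallback when the chosen coordinate folds back).

Along the curve the conserved total ``Gamma = B^T c`` singles out the
stoichiometric compatibility class: equilibria of the class ``Gamma*``
are the crossings of ``Gamma(t) = Gamma*``, and saddle-node (fold)
points — where equilibria appear or disappear in pairs — coincide with
the zeros of ``det G`` along the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .condition import g_matrix
from .manifold import ManifoldModel, manifold_equations, manifold_jacobian
from .network import NetworkError

__all__ = [
    "EquilibriumCurve",
    "FoldPoint",
    "find_branch_point",
    "trace_curve",
    "detect_folds",
    "count_equilibria",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20120703
FOLD_DET_RTOL = 1e-9


@dataclass(frozen=True)
class EquilibriumCurve:
    """Ordered samples of the positive equilibrium branch."""

    model: ManifoldModel
    param_name: str
    param_index: int           # species index of the parametrizing coordinate
    params: np.ndarray         # N
    C: np.ndarray              # N x m
    alpha: np.ndarray          # N x delta
    gamma: np.ndarray          # N x (m - s)
    detg: np.ndarray           # N

    def __len__(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class FoldPoint:
    """A zero of det G along the curve (saddle-node bifurcation)."""

    param: float
    c: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    det: float
    bracket: tuple[float, float]


# ---------------------------------------------------------------------------
# Solving the manifold with one coordinate pinned
# ---------------------------------------------------------------------------

def _solve_at_param(
    model: ManifoldModel,
    pidx: int,
    t: float,
    c_init: np.ndarray,
    alpha_init: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Damped Newton on H = 0 with ``c[pidx] = t`` held fixed."""
    m = model.net.n_species
    free_c = [i for i in range(m) if i != pidx]
    c = np.array(c_init, dtype=float)
    c[pidx] = t
    alpha = np.atleast_1d(np.array(alpha_init, dtype=float))
    if np.any(c <= 0):
        return None
    for _ in range(max_iter):
        H = manifold_equations(model, c, alpha)
        if np.linalg.norm(H) <= tol * (1.0 + np.linalg.norm(c)):
            return c, alpha
        Jc, Ja = manifold_jacobian(model, c, alpha)
        J = np.hstack([Jc[:, free_c], Ja])
        try:
            step = np.linalg.solve(J, -H)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -H, rcond=None)
        base = np.linalg.norm(H)
        damp = 1.0
        for _ in range(30):
            c_new = c.copy()
            c_new[free_c] += damp * step[: len(free_c)]
            a_new = alpha + damp * step[len(free_c):]
            if np.all(c_new > 0) and np.linalg.norm(
                    manifold_equations(model, c_new, a_new)) < base:
                break
            damp *= 0.5
        else:
            return None
        c, alpha = c_new, a_new
    H = manifold_equations(model, c, alpha)
    if np.linalg.norm(H) <= 1e-9 * (1.0 + np.linalg.norm(c)):
        return c, alpha
    return None


def find_branch_point(
    model: ManifoldModel,
    pidx: int,
    t: float,
    seed: int = DEFAULT_SEED,
    n_starts: int = 1000,
    log_range: tuple[float, float] = (-3.0, 3.0),
) -> tuple[np.ndarray, np.ndarray] | None:
    """Discover a point on the branch at ``c[pidx] = t``.

    Newton from a seeded log-uniform grid of starting concentrations
    (alpha started at zero, then at small random values).
    """
    rng = np.random.default_rng(seed)
    m = model.net.n_species
    delta = model.alpha_dim
    for trial in range(n_starts):
        c0 = 10.0 ** rng.uniform(*log_range, size=m)
        c0[pidx] = t
        if trial % 2 == 0 or delta == 0:
            a0 = np.zeros(delta)
        else:
            a0 = rng.normal(scale=10.0 ** rng.uniform(-2, 2), size=delta)
        sol = _solve_at_param(model, pidx, t, c0, a0)
        if sol is not None:
            return sol
    return None


# ---------------------------------------------------------------------------
# Curve tracing
# ---------------------------------------------------------------------------

def _default_param_index(model: ManifoldModel) -> int:
    """Species with the largest pivot in Y0 (heuristic default)."""
    return int(np.argmax(np.abs(np.diag(model.Y0)))) if model.Y0.size else 0


def trace_curve(
    model: ManifoldModel,
    param: str | None = None,
    prange: tuple[float, float] = (1e-2, 1e2),
    step: float = 0.05,
    seed: int = DEFAULT_SEED,
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> EquilibriumCurve:
    """Natural-parameter continuation of the equilibrium curve.

    Supported only for ``m - s = 1`` (one-dimensional manifolds); other
    networks should use the interval search.  The parametrizing species
    coordinate walks ``prange`` in steps of ``step``, warm-starting each
    Newton correction from the previous sample and halving the step on
    failure.  Stored per sample: ``(c, alpha, Gamma = B^T c, det G)``.
    """
    if model.report.manifold_dim != 1:
        raise NetworkError(
            f"curve tracing requires manifold dimension 1, got "
            f"{model.report.manifold_dim}")
    if param is None:
        pidx = _default_param_index(model)
    else:
        try:
            pidx = model.net.species.index(param)
        except ValueError:
            raise NetworkError(f"unknown species {param!r}") from None
    lo, hi = prange
    if not 0 < lo < hi:
        raise ValueError("parameter range must satisfy 0 < lo < hi")

    if start is None:
        start = find_branch_point(model, pidx, lo, seed=seed)
        if start is None:
            raise NetworkError(
                f"no starting point found on the branch at "
                f"{model.net.species[pidx]} = {lo} (1000 seeded Newton starts)")
    c, alpha = start

    params: list[float] = []
    Cs: list[np.ndarray] = []
    alphas: list[np.ndarray] = []

    t = lo
    current_step = step
    min_step = step * 2.0 ** -12
    while True:
        sol = _solve_at_param(model, pidx, t, c, alpha)
        if sol is None:
            # adaptive halving from the previous accepted sample
            if not params or current_step <= min_step:
                raise NetworkError(
                    f"continuation failed near {model.net.species[pidx]} = {t}")
            current_step *= 0.5
            t = params[-1] + current_step
            c, alpha = Cs[-1], alphas[-1]
            continue
        c, alpha = sol
        params.append(t)
        Cs.append(c.copy())
        alphas.append(alpha.copy())
        if t >= hi:
            break
        current_step = min(step, current_step * 2.0)
        t = min(t + current_step, hi)

    params_arr = np.array(params)
    C = np.vstack(Cs)
    A = np.vstack(alphas) if model.alpha_dim else np.zeros((len(params), 0))
    B = model.report.B
    gamma = C @ B
    detg = np.array([
        g_matrix(model, C[i], A[i]).det for i in range(len(params))])
    return EquilibriumCurve(
        model=model, param_name=model.net.species[pidx], param_index=pidx,
        params=params_arr, C=C, alpha=A, gamma=gamma, detg=detg,
    )


# ---------------------------------------------------------------------------
# Folds and equilibrium counting
# ---------------------------------------------------------------------------

def _curve_point(curve: EquilibriumCurve, t: float, i_near: int):
    return _solve_at_param(
        curve.model, curve.param_index, t,
        curve.C[i_near], curve.alpha[i_near])


def detect_folds(curve: EquilibriumCurve, det_rtol: float = FOLD_DET_RTOL) -> list[FoldPoint]:
    """Zeros of ``det G`` along the curve, refined by bisection.

    Each sign change between consecutive samples is bisected in the
    curve parameter until ``|det G| <= det_rtol * scale``; the refined
    points are the saddle-node bifurcations, where the curve is tangent
    to a compatibility class and ``Gamma`` is stationary.
    """
    model = curve.model
    folds: list[FoldPoint] = []
    for i in range(len(curve) - 1):
        d0, d1 = curve.detg[i], curve.detg[i + 1]
        if d0 == 0.0:
            continue
        if np.sign(d0) * np.sign(d1) < 0:
            a, b = curve.params[i], curve.params[i + 1]
            fa = d0
            best = None
            for _ in range(200):
                mid = 0.5 * (a + b)
                sol = _curve_point(curve, mid, i)
                if sol is None:
                    break
                ev = g_matrix(model, sol[0], sol[1])
                best = (mid, sol, ev)
                if abs(ev.det) <= det_rtol * ev.scale or (b - a) < 1e-15 * max(1.0, abs(mid)):
                    break
                if np.sign(ev.det) == np.sign(fa):
                    a, fa = mid, ev.det
                else:
                    b = mid
            if best is not None:
                mid, (c, alpha), ev = best
                folds.append(FoldPoint(
                    param=mid, c=c, alpha=alpha,
                    gamma=model.report.B.T @ c, det=ev.det,
                    bracket=(curve.params[i], curve.params[i + 1]),
                ))
    return folds


def count_equilibria(
    curve: EquilibriumCurve, gamma_value: float, tol: float = 1e-10,
    refine: bool = True,
) -> tuple[int, list[tuple[np.ndarray, np.ndarray]]]:
    """Number of positive equilibria in the compatibility class ``Gamma``.

    Counts the crossings of ``Gamma(t) = gamma_value`` along the traced
    curve (bracketed bisection per sign change).  Requires a scalar
    conserved total (``m - s = 1``).  Returns the refined equilibrium
    points as ``(c, alpha)`` pairs; outside the curve's Gamma range the
    count is 0.  With ``refine=False`` crossings are counted from the
    stored samples only (cheap, bracket-resolution accuracy).
    """
    if curve.gamma.shape[1] != 1:
        raise NetworkError("equilibrium counting requires a scalar conserved total")
    g = curve.gamma[:, 0] - gamma_value
    points: list[tuple[np.ndarray, np.ndarray]] = []
    model = curve.model
    B = model.report.B

    for i in range(len(curve) - 1):
        gi, gj = g[i], g[i + 1]
        if abs(gi) <= tol * max(1.0, abs(gamma_value)):
            if not points or abs(curve.params[i] - _last_param(points, curve)) > 1e-9:
                points.append((curve.C[i].copy(), curve.alpha[i].copy()))
            continue
        if np.sign(gi) * np.sign(gj) < 0:
            if not refine:
                points.append((curve.C[i].copy(), curve.alpha[i].copy()))
                continue
            a, b = curve.params[i], curve.params[i + 1]
            fa = gi
            sol = None
            for _ in range(200):
                mid = 0.5 * (a + b)
                sol = _curve_point(curve, mid, i)
                if sol is None:
                    break
                val = float((B.T @ sol[0])[0]) - gamma_value
                if abs(val) <= tol * max(1.0, abs(gamma_value)):
                    break
                if np.sign(val) == np.sign(fa):
                    a, fa = mid, val
                else:
                    b = mid
            if sol is not None:
                points.append(sol)
    # endpoint exactly on the class
    if len(curve) and abs(g[-1]) <= tol * max(1.0, abs(gamma_value)):
        points.append((curve.C[-1].copy(), curve.alpha[-1].copy()))
    return len(points), points


def _last_param(points, curve: EquilibriumCurve) -> float:
    c, _ = points[-1]
    return float(c[curve.param_index])
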
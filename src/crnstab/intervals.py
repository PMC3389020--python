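"""Reliable interval arithmetic and SIVIA-style branch-and-prune search.

The multistationarity condition is a conjunction of equalities
(``H(c, alpha) = 0`` and ``det G(c, alpha) = 0``) and domain constraints
(``c > 0``, ``alpha`` bounded away from 0) over a user-chosen set of
free variables (rate constants, concentrations, deficiency parameters).
This module encloses the solution set by an *outer subpaving*: a finite
union of non-overlapping boxes guaranteed to contain every true
solution inside the initial search box.

Soundness model: every elementary operation computes with ordinary
round-to-nearest floats and then widens the result outward by a fixed
number of ulps (default 4), a conservative stand-in for directed
rounding.  Enclosures are therefore never tighter than the true range.

The solver itself is deterministic plain SIVIA: evaluate every equality
enclosure on a box; discard the box if any enclosure excludes zero (or
the domain constraints fail on the whole box); accept it once its
maximal relative width drops below ``eps``; otherwise bisect the widest
relative dimension and recurse.  No contractor propagation is applied —
pruning strength is traded for simplicity, reliability is unaffected.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .manifold import ManifoldModel, spanning_in_trees

__all__ = [
    "Interval",
    "Box",
    "CSProblem",
    "Subpaving",
    "interval_extension",
    "solve_csp",
    "MultistatConstraints",
    "build_multistat_csp",
    "variable_names",
    "paving_contains",
    "export_paving",
    "export_paving_csv",
    "load_paving",
]

#: outward widening, in ulps per elementary operation
ULPS = 4

_INF = math.inf


def _down(x: float) -> float:
    for _ in range(ULPS):
        x = math.nextafter(x, -_INF)
    return x


def _up(x: float) -> float:
    for _ in range(ULPS):
        x = math.nextafter(x, _INF)
    return x


class Interval:
    """Closed interval ``[lo, hi]`` with outward-rounded arithmetic."""

    __slots__ = ("lo", "hi")

    def __init__(self, lo: float, hi: float | None = None, exact: bool = False):
        if hi is None:
            hi = lo
        if not lo <= hi:
            raise ValueError(f"invalid interval [{lo}, {hi}]")
        self.lo = float(lo)
        self.hi = float(hi)

    # -- constructors -------------------------------------------------------

    @staticmethod
    def entire() -> "Interval":
        return Interval(-_INF, _INF)

    # -- predicates ---------------------------------------------------------

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def contains_zero(self) -> bool:
        return self.lo <= 0.0 <= self.hi

    def is_subset(self, other: "Interval") -> bool:
        return other.lo <= self.lo and self.hi <= other.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def mid(self) -> float:
        if math.isinf(self.lo) or math.isinf(self.hi):
            return 0.0
        return 0.5 * (self.lo + self.hi)

    @property
    def mag(self) -> float:
        """Magnitude: max |x| over the interval."""
        return max(abs(self.lo), abs(self.hi))

    @property
    def mig(self) -> float:
        """Mignitude: min |x| over the interval (0 if it contains 0)."""
        if self.contains_zero():
            return 0.0
        return min(abs(self.lo), abs(self.hi))

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Interval":
        return x if isinstance(x, Interval) else Interval(float(x), float(x))

    def __neg__(self) -> "Interval":
        return Interval(-self.hi, -self.lo)

    def __add__(self, other) -> "Interval":
        o = Interval._coerce(other)
        return Interval(_down(self.lo + o.lo), _up(self.hi + o.hi))

    __radd__ = __add__

    def __sub__(self, other) -> "Interval":
        o = Interval._coerce(other)
        return Interval(_down(self.lo - o.hi), _up(self.hi - o.lo))

    def __rsub__(self, other) -> "Interval":
        return Interval._coerce(other) - self

    def __mul__(self, other) -> "Interval":
        o = Interval._coerce(other)
        cands = (self.lo * o.lo, self.lo * o.hi, self.hi * o.lo, self.hi * o.hi)
        return Interval(_down(min(cands)), _up(max(cands)))

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Interval":
        o = Interval._coerce(other)
        if o.contains_zero():
            raise ZeroDivisionError(
                f"division by interval [{o.lo}, {o.hi}] containing zero")
        cands = (self.lo / o.lo, self.lo / o.hi, self.hi / o.lo, self.hi / o.hi)
        return Interval(_down(min(cands)), _up(max(cands)))

    def __rtruediv__(self, other) -> "Interval":
        return Interval._coerce(other) / self

    def __pow__(self, n: int) -> "Interval":
        if not isinstance(n, int) or n < 0:
            raise ValueError("only nonnegative integer powers are supported")
        if n == 0:
            return Interval(1.0, 1.0)
        a, b = self.lo ** n, self.hi ** n
        lo, hi = min(a, b), max(a, b)
        if n % 2 == 0 and self.contains_zero():
            return Interval(0.0, _up(hi))   # the zero bound is exact
        return Interval(_down(lo), _up(hi))

    def hull(self, other: "Interval") -> "Interval":
        return Interval(min(self.lo, other.lo), max(self.hi, other.hi))

    def __repr__(self) -> str:
        return f"[{self.lo:.17g}, {self.hi:.17g}]"


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Cartesian product of closed intervals over named variables."""

    names: tuple[str, ...]
    intervals: tuple[Interval, ...]

    def __post_init__(self):
        if len(self.names) != len(self.intervals):
            raise ValueError("names and intervals length mismatch")

    def __getitem__(self, name: str) -> Interval:
        return self.intervals[self.names.index(name)]

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.intervals])

    def rel_widths(self) -> np.ndarray:
        """Width scaled by max(1, magnitude) per dimension."""
        return np.array(
            [iv.width / max(1.0, iv.mag) for iv in self.intervals])

    @property
    def max_rel_width(self) -> float:
        return float(self.rel_widths().max())

    def volume(self) -> float:
        return float(np.prod(self.widths()))

    def midpoint(self) -> np.ndarray:
        return np.array([iv.mid for iv in self.intervals])

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float)
        if point.shape != (len(self.names),):
            raise ValueError(
                f"point dimension {point.shape} != box dimension {len(self.names)}")
        return all(iv.contains(x) for iv, x in zip(self.intervals, point))

    def bisect(self, dim: int) -> tuple["Box", "Box"]:
        iv = self.intervals[dim]
        mid = iv.mid
        left = list(self.intervals)
        right = list(self.intervals)
        left[dim] = Interval(iv.lo, mid)
        right[dim] = Interval(mid, iv.hi)
        return (Box(self.names, tuple(left)), Box(self.names, tuple(right)))


def interval_extension(expr, box: Box, fixed: dict[str, float] | None = None) -> Interval:
    """Evaluate an interval-arithmetic expression over a box.

    ``expr`` maps an environment (variable name -> Interval) to an
    Interval; by construction the result encloses the true range of the
    underlying real function over the box.
    """
    env = {name: iv for name, iv in zip(box.names, box.intervals)}
    for name, value in (fixed or {}).items():
        env[name] = Interval(value, value)
    return expr(env)


# ---------------------------------------------------------------------------
# Interval determinants
# ---------------------------------------------------------------------------

def interval_det(M: list[list[Interval]]) -> Interval:
    """Enclosure of the determinant of an interval matrix.

    Cofactor expansion for sizes <= 5; interval LU with mignitude
    pivoting above that.  If LU cannot find a pivot excluding zero the
    whole real line is returned (no conclusion possible — still sound).
    """
    n = len(M)
    if n <= 5:
        return _det_cofactor(M)
    return _det_lu(M)


def _det_cofactor(M: list[list[Interval]]) -> Interval:
    n = len(M)
    if n == 1:
        return M[0][0]
    if n == 2:
        return M[0][0] * M[1][1] - M[0][1] * M[1][0]
    total = Interval(0.0, 0.0)
    for i in range(n):
        a = M[i][0]
        if a.lo == 0.0 and a.hi == 0.0:
            continue
        minor = [row[1:] for r, row in enumerate(M) if r != i]
        term = a * _det_cofactor(minor)
        total = total + term if i % 2 == 0 else total - term
    return total


def _det_lu(M: list[list[Interval]]) -> Interval:
    n = len(M)
    A = [row[:] for row in M]
    det = Interval(1.0, 1.0)
    sign = 1
    for col in range(n):
        pivot_row = max(range(col, n), key=lambda r: A[r][col].mig)
        if A[pivot_row][col].mig == 0.0:
            return Interval.entire()
        if pivot_row != col:
            A[col], A[pivot_row] = A[pivot_row], A[col]
            sign = -sign
        pivot = A[col][col]
        det = det * pivot
        for r in range(col + 1, n):
            factor = A[r][col] / pivot
            for cc in range(col + 1, n):
                A[r][cc] = A[r][cc] - factor * A[col][cc]
    return det if sign > 0 else -det


def _solve_interval_linear(
    A: list[list[Interval]], b: list[Interval]
) -> list[Interval] | None:
    """Gaussian elimination with mignitude pivoting; None if a pivot
    contains zero (caller falls back to a trivial enclosure)."""
    n = len(A)
    A = [row[:] + [bi] for row, bi in zip(A, b)]
    for col in range(n):
        pivot_row = max(range(col, n), key=lambda r: A[r][col].mig)
        if A[pivot_row][col].mig == 0.0:
            return None
        if pivot_row != col:
            A[col], A[pivot_row] = A[pivot_row], A[col]
        for r in range(col + 1, n):
            factor = A[r][col] / A[col][col]
            for cc in range(col + 1, n + 1):
                A[r][cc] = A[r][cc] - factor * A[col][cc]
    x: list[Interval] = [Interval(0.0)] * n
    for row in range(n - 1, -1, -1):
        acc = A[row][n]
        for cc in range(row + 1, n):
            acc = acc - A[row][cc] * x[cc]
        x[row] = acc / A[row][row]
    return x


# ---------------------------------------------------------------------------
# Model-specific constraints: H components and det G over (K, c, alpha)
# ---------------------------------------------------------------------------

def variable_names(model: ManifoldModel) -> dict[str, list[str]]:
    """Canonical variable names for the CSP over ``(K, c, alpha)``.

    Rate constants are ``k1..kR`` in reaction order, concentrations use
    the species names, deficiency parameters are ``alpha`` (``alpha1..``
    when ``delta > 1``).
    """
    k_names = [f"k{i + 1}" for i in range(model.net.n_reactions)]
    c_names = list(model.net.species)
    if model.alpha_dim == 1:
        a_names = ["alpha"]
    else:
        a_names = [f"alpha{j + 1}" for j in range(model.alpha_dim)]
    return {"k": k_names, "c": c_names, "alpha": a_names}


class MultistatConstraints:
    """Interval evaluators for the manifold residuals and ``det G``.

    When rate constants are free variables the per-class kernel entries
    ``rho`` are evaluated through their matrix-tree (spanning in-tree)
    polynomials, and the particular solutions ``eta`` through an
    interval linear solve in the reference-entry-zero gauge
    (``eta[ref] = 0``); both make every constraint an explicit interval
    expression in ``(K, c, alpha)``.  Gauge freedom in ``eta`` does not
    change ``H`` or ``det G`` as functions, so this is consistent with
    the minimum-norm gauge used by the point-evaluation path.
    """

    def __init__(self, model: ManifoldModel):
        self.model = model
        names = variable_names(model)
        self.k_names = names["k"]
        self.c_names = names["c"]
        self.a_names = names["alpha"]
        net = model.net
        self._trees: list[dict[int, list[tuple[int, ...]]]] = []
        for cls in model.report.linkage_classes:
            members = set(cls)
            edges = [(i, j, r) for r, (i, j, _) in enumerate(net.reactions)
                     if i in members]
            self._trees.append(
                {root: spanning_in_trees(cls, edges, root) for root in cls})
        self._k_cache: list[Interval] | None = None
        self._kin_cache: tuple[dict[int, Interval], list[list[Interval]]] | None = None

    # -- kinetic quantities -------------------------------------------------

    def _k_intervals(self, env) -> list[Interval]:
        return [Interval._coerce(env[name]) for name in self.k_names]

    def _rho(self, K: list[Interval]) -> dict[int, Interval]:
        rho: dict[int, Interval] = {}
        for trees_by_root in self._trees:
            for root, trees in trees_by_root.items():
                acc = Interval(0.0, 0.0)
                for tree in trees:
                    term = Interval(1.0, 1.0)
                    for ridx in tree:
                        term = term * K[ridx]
                    acc = acc + term
                rho[root] = acc
        return rho

    def _eta(self, K: list[Interval]) -> list[list[Interval]]:
        """eta columns (n x delta) in the eta[ref] = 0 gauge."""
        model = self.model
        net = model.net
        n = net.n_complexes
        delta = model.alpha_dim
        eta = [[Interval(0.0, 0.0) for _ in range(delta)] for _ in range(n)]
        if delta == 0:
            return eta
        for ci, cls in enumerate(model.report.linkage_classes):
            ref = model.ref_complexes[ci]
            unknowns = [p for p in cls if p != ref]
            if not unknowns:
                continue
            members = set(cls)
            # class block of A_k restricted to non-reference rows/columns
            A = [[Interval(0.0, 0.0) for _ in unknowns] for _ in unknowns]
            for r, (i, j, _) in enumerate(net.reactions):
                if i not in members:
                    continue
                k = K[r]
                if i in unknowns:
                    ii = unknowns.index(i)
                    A[ii][ii] = A[ii][ii] - k
                    if j in unknowns:
                        A[unknowns.index(j)][ii] = A[unknowns.index(j)][ii] + k
            for j in range(delta):
                b = [Interval(model.omega[p, j], model.omega[p, j])
                     for p in unknowns]
                sol = _solve_interval_linear(A, b)
                if sol is None:
                    for p in unknowns:
                        eta[p][j] = Interval.entire()
                else:
                    for p, val in zip(unknowns, sol):
                        eta[p][j] = val
        return eta

    def _kinetics(self, env) -> tuple[dict[int, Interval], list[list[Interval]]]:
        K = self._k_intervals(env)
        if self._kin_cache is not None and all(
                k.lo == c.lo and k.hi == c.hi
                for k, c in zip(K, self._k_cache)):
            return self._kin_cache
        rho = self._rho(K)
        eta = self._eta(K)
        self._k_cache = K
        self._kin_cache = (rho, eta)
        return rho, eta

    # -- expressions --------------------------------------------------------

    def _psi_of(self, p: int, env) -> Interval:
        acc = Interval(1.0, 1.0)
        for coeff, name in zip(self.model.net.complexes[p], self.c_names):
            if coeff:
                acc = acc * (Interval._coerce(env[name]) ** int(coeff))
        return acc

    def h_component(self, row: int, env) -> Interval:
        """Enclosure of H_row over the environment (eta[ref]=0 gauge)."""
        model = self.model
        p = model.nonref[row]
        r = model.ref_of(p)
        rho, eta = self._kinetics(env)
        ratio = rho[p] / rho[r]
        val = self._psi_of(p, env) - ratio * self._psi_of(r, env)
        for j, a_name in enumerate(self.a_names):
            val = val - Interval._coerce(env[a_name]) * eta[p][j]
        return val

    def g_matrix(self, env) -> list[list[Interval]]:
        model = self.model
        net = model.net
        Y = net.Y
        rho, eta = self._kinetics(env)
        c = [Interval._coerce(env[name]) for name in self.c_names]
        rows: list[list[Interval]] = []
        for p in model.nonref:
            r = model.ref_of(p)
            ratio = rho[p] / rho[r]
            psi_p = self._psi_of(p, env)
            psi_r = self._psi_of(r, env)
            row = []
            for k in range(net.n_species):
                term = Interval(0.0, 0.0)
                if Y[k, p]:
                    term = term + psi_p * float(Y[k, p])
                if Y[k, r]:
                    term = term - ratio * (psi_r * float(Y[k, r]))
                row.append(term / c[k])
            for j in range(model.alpha_dim):
                # J_alpha = ratio * eta[r] - eta[p]; eta[ref] = 0 in this gauge
                row.append(-eta[p][j])
            rows.append(row)
        B = model.report.B
        for col in range(B.shape[1]):
            row = [Interval(B[k, col], B[k, col]) for k in range(net.n_species)]
            row.extend(Interval(0.0, 0.0) for _ in range(model.alpha_dim))
            rows.append(row)
        return rows

    def det_g(self, env) -> Interval:
        return interval_det(self.g_matrix(env))

    def constraints(self, include_det: bool = True):
        """Named equality constraints: every H component, then det G."""
        cons = [(f"H{row + 1}", lambda env, row=row: self.h_component(row, env))
                for row in range(len(self.model.nonref))]
        if include_det:
            cons.append(("detG", self.det_g))
        return cons


# ---------------------------------------------------------------------------
# The constraint satisfaction problem and SIVIA solver
# ---------------------------------------------------------------------------

@dataclass
class CSProblem:
    """Branch-and-prune problem: equalities + domain over a start box."""

    box: Box
    equalities: list          # list of (name, callable(env) -> Interval)
    fixed: dict[str, float] = field(default_factory=dict)
    positive: tuple[str, ...] = ()      # variables required > 0
    alpha_vars: tuple[str, ...] = ()    # variables required |x| >= eps_alpha
    eps: float = 0.05
    eps_alpha: float = 1e-9
    max_boxes: int = 2_000_000

    def __post_init__(self):
        if not self.box.names:
            raise ValueError("at least one free variable is required")
        for name in self.positive:
            if name in self.box.names and self.box[name].lo <= 0:
                raise ValueError(f"positive variable {name!r} has lo <= 0")


@dataclass
class Subpaving:
    """Outer enclosure of the CSP solution set.

    ``boxes`` are pairwise non-overlapping (shared faces allowed).  When
    the iteration budget ran out, the unprocessed boxes are *included*
    in the union and ``exhaustive`` is False — the reliability contract
    (every true solution lies in the union) holds either way.
    """

    names: tuple[str, ...]
    boxes: list[Box]
    exhaustive: bool = True
    processed: int = 0
    discarded: int = 0
    bisections: int = 0

    def volume(self) -> float:
        return float(sum(b.volume() for b in self.boxes))

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float)
        if point.shape != (len(self.names),):
            raise ValueError("point dimension mismatch")
        return any(b.contains(point) for b in self.boxes)


def solve_csp(problem: CSProblem) -> Subpaving:
    """Deterministic SIVIA / branch-and-prune outer enclosure."""
    fixed_env = {name: Interval(v, v) for name, v in problem.fixed.items()}
    names = problem.box.names
    alpha_idx = [names.index(a) for a in problem.alpha_vars if a in names]

    accepted: list[Box] = []
    stack = [problem.box]
    processed = discarded = bisections = 0
    exhausted = False

    while stack:
        if processed >= problem.max_boxes:
            exhausted = True
            break
        box = stack.pop()
        processed += 1

        # domain constraint: discard when |alpha| < eps_alpha over the whole box
        if any(box.intervals[i].mag < problem.eps_alpha for i in alpha_idx):
            discarded += 1
            continue

        env = dict(fixed_env)
        env.update(zip(names, box.intervals))
        feasible = True
        for _, fn in problem.equalities:
            if not fn(env).contains_zero():
                feasible = False
                break
        if not feasible:
            discarded += 1
            continue

        if box.max_rel_width <= problem.eps:
            accepted.append(box)
            continue

        rel = box.rel_widths()
        dim = int(np.argmax(rel))
        left, right = box.bisect(dim)
        bisections += 1
        stack.append(right)
        stack.append(left)

    if exhausted:
        accepted.extend(stack)
    return Subpaving(
        names=names, boxes=accepted, exhaustive=not exhausted,
        processed=processed, discarded=discarded, bisections=bisections,
    )


def build_multistat_csp(
    model: ManifoldModel,
    free: dict[str, tuple[float, float]],
    fixed: dict[str, float] | None = None,
    eps: float = 0.05,
    eps_alpha: float = 1e-9,
    max_boxes: int = 2_000_000,
    include_det: bool = True,
) -> CSProblem:
    """Assemble the multistationarity CSP over designated free variables.

    ``free`` maps variable names (see :func:`variable_names`) to their
    search intervals; every remaining variable of ``(K, c, alpha)`` must
    appear in ``fixed`` except rate constants, which default to the
    model's own ``K``.
    """
    names = variable_names(model)
    all_vars = names["k"] + names["c"] + names["alpha"]
    fixed = dict(fixed or {})
    for i, k_name in enumerate(names["k"]):
        if k_name not in free and k_name not in fixed:
            fixed[k_name] = float(model.K[i])
    missing = [v for v in all_vars if v not in free and v not in fixed]
    if missing:
        raise ValueError(f"variables neither fixed nor free: {missing}")
    unknown = [v for v in list(free) + list(fixed) if v not in all_vars]
    if unknown:
        raise ValueError(f"unknown variables: {unknown}")

    order = [v for v in all_vars if v in free]
    box = Box(tuple(order), tuple(Interval(*free[v]) for v in order))
    cons = MultistatConstraints(model)
    positive = tuple(v for v in names["k"] + names["c"] if v in free)
    for v in positive:
        if free[v][0] <= 0:
            raise ValueError(f"free variable {v!r} needs a positive lower bound")
    return CSProblem(
        box=box,
        equalities=cons.constraints(include_det=include_det),
        fixed=fixed,
        positive=positive,
        alpha_vars=tuple(names["alpha"]),
        eps=eps,
        eps_alpha=eps_alpha,
        max_boxes=max_boxes,
    )


# ---------------------------------------------------------------------------
# Paving queries and serialization
# ---------------------------------------------------------------------------

def paving_contains(paving: Subpaving, point) -> bool:
    return paving.contains(point)


def export_paving(paving: Subpaving, path) -> None:
    doc = {
        "variables": list(paving.names),
        "exhaustive": paving.exhaustive,
        "stats": {
            "processed": paving.processed,
            "discarded": paving.discarded,
            "bisections": paving.bisections,
            "accepted": len(paving.boxes),
        },
        "boxes": [
            [[f"{iv.lo:.17g}", f"{iv.hi:.17g}"] for iv in b.intervals]
            for b in paving.boxes
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def export_paving_csv(paving: Subpaving, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = []
        for name in paving.names:
            header += [f"{name}_lo", f"{name}_hi"]
        writer.writerow(header)
        for b in paving.boxes:
            row = []
            for iv in b.intervals:
                row += [f"{iv.lo:.17g}", f"{iv.hi:.17g}"]
            writer.writerow(row)


def load_paving(path) -> Subpaving:
    with open(path) as fh:
        doc = json.load(fh)
    names = tuple(doc["variables"])
    boxes = [
        Box(names, tuple(Interval(float(lo), float(hi)) for lo, hi in entry))
        for entry in doc["boxes"]
    ]
    stats = doc.get("stats", {})
    return Subpaving(
        names=names, boxes=boxes, exhaustive=doc.get("exhaustive", True),
        processed=stats.get("processed", 0),
        discarded=stats.get("discarded", 0),
        bisections=stats.get("bisections", 0),
    )
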
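"""Mass-action reaction networks and their CRNT structural analysis.

A reaction network is a directed graph whose nodes are *complexes*
(formal nonnegative-integer combinations of species, e.g. ``A + B`` or
``2A``) and whose edges are mass-action reaction steps with positive
rate constants.  This module parses networks from a small text DSL or a
JSON mirror and computes the classical structural quantities of
Chemical Reaction Network Theory:

* linkage classes (connected components of the complex graph),
* strong terminal linkage classes and weak reversibility,
* the stoichiometric subspace ``S``, its dimension ``s`` and a basis
  ``B`` of the orthogonal complement (conservation laws ``B^T c = const``),
* the deficiency ``delta = n - l - s`` and the deficiency-zero verdict
  that structurally excludes multistationarity.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NetworkError",
    "ParseError",
    "ReactionNetwork",
    "StructuralReport",
    "parse_network",
    "network_from_reactions",
    "write_network",
    "write_network_json",
    "linkage_classes",
    "terminal_strong_classes",
    "stoichiometry",
    "structural_report",
]

#: Relative SVD threshold used for every numerical rank decision.
RANK_RTOL = 1e-10

#: Largest molecularity coefficient accepted in a complex.
MAX_COEFF = 99


class NetworkError(ValueError):
    """Invalid network structure or data."""


class ParseError(NetworkError):
    """Syntax error in the network DSL, with line/column location."""

    def __init__(self, message: str, line: int, column: int = 0):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionNetwork:
    """A validated mass-action reaction network.

    Attributes
    ----------
    species:
        Ordered species names; order is declaration order and fixes the
        row order of every species-space vector and matrix.
    complexes:
        Ordered tuple of molecularity vectors (one ``m``-tuple of
        nonnegative ints per complex).  The ordering is canonical:
        ascending total molecularity, ties broken by descending
        coefficient tuple, so that e.g. (A, B, C, 2A, A+B).
    reactions:
        Tuple of ``(source_index, target_index, k)`` directed steps with
        strictly positive rate constants.
    """

    species: tuple[str, ...]
    complexes: tuple[tuple[int, ...], ...]
    reactions: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        m = len(self.species)
        if m < 1:
            raise NetworkError("network needs at least one species")
        if len(self.complexes) < 2:
            raise NetworkError("network needs at least two complexes")
        if len(set(self.complexes)) != len(self.complexes):
            raise NetworkError("complexes must be pairwise distinct")
        for y in self.complexes:
            if len(y) != m or any(c < 0 or c > MAX_COEFF for c in y):
                raise NetworkError(f"bad molecularity vector {y}")
        seen = set()
        for i, j, k in self.reactions:
            if not (0 <= i < len(self.complexes)) or not (0 <= j < len(self.complexes)):
                raise NetworkError(f"reaction ({i}, {j}) references unknown complex")
            if i == j:
                raise NetworkError(
                    f"source equals target complex in reaction {self.complex_name(i)} "
                    f"-> {self.complex_name(j)}"
                )
            if not k > 0:
                raise NetworkError(f"nonpositive rate constant {k} on reaction {i}->{j}")
            if (i, j) in seen:
                raise NetworkError(
                    f"duplicate reaction {self.complex_name(i)} -> {self.complex_name(j)}"
                )
            seen.add((i, j))

    # -- derived views ------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def Y(self) -> np.ndarray:
        """Molecularity matrix: m x n, columns are the complexes."""
        return np.array(self.complexes, dtype=float).T

    @property
    def K(self) -> np.ndarray:
        """Rate constants in reaction order."""
        return np.array([k for _, _, k in self.reactions])

    def targets_of(self, i: int) -> list[int]:
        """Index set of complexes reachable from complex ``i`` in one step."""
        return [j for a, j, _ in self.reactions if a == i]

    def complex_name(self, i: int) -> str:
        terms = []
        for coeff, name in zip(self.complexes[i], self.species):
            if coeff == 0:
                continue
            terms.append(name if coeff == 1 else f"{coeff}{name}")
        return " + ".join(terms) if terms else "0"


@dataclass(frozen=True)
class StructuralReport:
    """All structural CRNT quantities of a network."""

    net: ReactionNetwork
    linkage_classes: tuple[tuple[int, ...], ...]
    terminal_strong_classes: tuple[tuple[tuple[int, ...], ...], ...]
    weakly_reversible: bool
    single_terminal_per_class: bool
    Y: np.ndarray
    stoich_basis: np.ndarray          # m x s, orthonormal basis of S
    s: int
    B: np.ndarray                     # m x (m - s), conservation-law basis
    omega_indicators: np.ndarray      # l x n, 0/1 rows per linkage class
    deficiency: int
    manifold_dim: int                 # m - s
    layout_class: str                 # proper / overdimensioned / underdimensioned
    multistationarity_excluded: bool

    @property
    def l(self) -> int:
        return len(self.linkage_classes)


# ---------------------------------------------------------------------------
# Parsing: text DSL and JSON mirror
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"\s*(\d+)?\s*([A-Za-z_][A-Za-z0-9_]*)\s*$")


def _canonical_key(y: tuple[int, ...]):
    # lighter complexes first; ties: heavier in earlier-declared species first
    return (sum(y), tuple(-c for c in y))


def _parse_complex(text: str, species_index: dict[str, int],
                   line: int) -> tuple[int, ...]:
    m = len(species_index)
    vec = [0] * m
    if text.strip() in ("0", ""):
        raise ParseError("empty complex is not supported", line)
    for term in text.split("+"):
        match = _TERM_RE.match(term)
        if not match:
            raise ParseError(f"cannot parse complex term {term.strip()!r}", line)
        coeff = int(match.group(1)) if match.group(1) else 1
        name = match.group(2)
        if name not in species_index:
            raise ParseError(f"unknown species {name!r}", line)
        if coeff <= 0 or coeff > MAX_COEFF:
            raise ParseError(f"coefficient {coeff} out of range 1..{MAX_COEFF}", line)
        vec[species_index[name]] += coeff
    return tuple(vec)


def network_from_reactions(
    species: list[str],
    reactions: list[tuple[dict[str, int], dict[str, int], float]],
) -> ReactionNetwork:
    """Build a network from (source map, target map, k) triples.

    Complexes are deduplicated by molecularity vector and put into the
    canonical ordering; reaction indices refer to that ordering.
    """
    species = list(species)
    if len(set(species)) != len(species):
        raise NetworkError("duplicate species name")
    sidx = {name: i for i, name in enumerate(species)}
    m = len(species)

    def as_vec(d: dict[str, int]) -> tuple[int, ...]:
        vec = [0] * m
        for name, coeff in d.items():
            if name not in sidx:
                raise NetworkError(f"unknown species {name!r}")
            vec[sidx[name]] += int(coeff)
        return tuple(vec)

    raw = [(as_vec(src), as_vec(tgt), float(k)) for src, tgt, k in reactions]
    for src, tgt, _ in raw:
        if src == tgt:
            raise NetworkError("source equals target complex in a reaction")
    cset = {v for src, tgt, _ in raw for v in (src, tgt)}
    complexes = tuple(sorted(cset, key=_canonical_key))
    cindex = {v: i for i, v in enumerate(complexes)}
    steps = tuple((cindex[src], cindex[tgt], k) for src, tgt, k in raw)
    return ReactionNetwork(tuple(species), complexes, steps)


def parse_network(text: str) -> ReactionNetwork:
    """Parse the ``.crn`` DSL (or its JSON mirror) into a network.

    DSL grammar (line oriented; ``;`` also separates statements and
    ``#`` starts a comment)::

        species A B C
        reaction A <-> 2A : 8.5, 1
        reaction B -> C : 0.2

    The ``reaction`` keyword is optional.  Reversible arrows ``<->``
    expand into two directed steps with ``k_fwd, k_rev``.
    """
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _network_from_json(json.loads(text))

    species: list[str] = []
    sidx: dict[str, int] = {}
    raw: list[tuple[tuple[int, ...], tuple[int, ...], float, int]] = []

    lines = text.splitlines() or [text]
    for lineno, line in enumerate(lines, start=1):
        line = line.split("#", 1)[0]
        for stmt in line.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            if stmt.startswith("species"):
                for name in stmt[len("species"):].split():
                    if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
                        raise ParseError(f"bad species name {name!r}", lineno)
                    if name in sidx:
                        raise ParseError(f"duplicate species {name!r}", lineno)
                    sidx[name] = len(species)
                    species.append(name)
                continue
            if stmt.startswith("reaction"):
                stmt = stmt[len("reaction"):].strip()
            if ":" not in stmt:
                raise ParseError("reaction needs ': <rate constants>'", lineno)
            arrow_part, k_part = stmt.rsplit(":", 1)
            reversible = "<->" in arrow_part
            sep = "<->" if reversible else "->"
            pieces = arrow_part.split(sep)
            if len(pieces) != 2:
                raise ParseError(f"expected one {sep!r} arrow", lineno)
            if not species:
                raise ParseError("species must be declared before reactions", lineno)
            src = _parse_complex(pieces[0], sidx, lineno)
            tgt = _parse_complex(pieces[1], sidx, lineno)
            if src == tgt:
                raise ParseError("source equals target complex", lineno)
            ks = [p.strip() for p in k_part.split(",")]
            expected = 2 if reversible else 1
            if len(ks) != expected:
                raise ParseError(
                    f"expected {expected} rate constant(s), got {len(ks)}", lineno)
            try:
                kvals = [float(p) for p in ks]
            except ValueError:
                raise ParseError(f"bad rate constant in {k_part.strip()!r}", lineno) from None
            for k in kvals:
                if not k > 0:
                    raise ParseError(f"nonpositive rate constant {k}", lineno)
            raw.append((src, tgt, kvals[0], lineno))
            if reversible:
                raw.append((tgt, src, kvals[1], lineno))

    if not raw:
        raise ParseError("no reactions found", len(lines))
    cset = {v for src, tgt, _, _ in raw for v in (src, tgt)}
    complexes = tuple(sorted(cset, key=_canonical_key))
    cindex = {v: i for i, v in enumerate(complexes)}
    steps = tuple((cindex[src], cindex[tgt], k) for src, tgt, k, _ in raw)
    return ReactionNetwork(tuple(species), complexes, steps)


def _network_from_json(doc: dict) -> ReactionNetwork:
    reactions = [(r["from"], r["to"], float(r["k"])) for r in doc["reactions"]]
    return network_from_reactions(list(doc["species"]), reactions)


def write_network(net: ReactionNetwork) -> str:
    """Serialize to the DSL in canonical ordering (round-trip exact)."""
    lines = ["species " + " ".join(net.species)]
    for i, j, k in net.reactions:
        lines.append(
            f"reaction {net.complex_name(i)} -> {net.complex_name(j)} : {k!r}")
    return "\n".join(lines) + "\n"


def write_network_json(net: ReactionNetwork) -> str:
    def as_map(idx):
        return {name: c for c, name in zip(net.complexes[idx], net.species) if c}

    doc = {
        "species": list(net.species),
        "reactions": [
            {"from": as_map(i), "to": as_map(j), "k": k}
            for i, j, k in net.reactions
        ],
    }
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# Graph structure
# ---------------------------------------------------------------------------

def _digraph(net: ReactionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_complexes))
    g.add_edges_from((i, j) for i, j, _ in net.reactions)
    return g


def linkage_classes(net: ReactionNetwork) -> tuple[tuple[int, ...], ...]:
    """Connected components of the undirected complex graph.

    Ordered by smallest member index; members sorted ascending.
    """
    comps = nx.connected_components(_digraph(net).to_undirected())
    classes = sorted((tuple(sorted(c)) for c in comps), key=lambda c: c[0])
    return tuple(classes)


def terminal_strong_classes(
    net: ReactionNetwork,
) -> tuple[tuple[tuple[tuple[int, ...], ...], ...], bool, bool]:
    """Terminal strongly connected components, grouped by linkage class.

    Returns ``(terminal_per_class, weakly_reversible, single_terminal)``.
    A strong component is *terminal* when no reaction leaves it.  A
    linkage class is weakly reversible iff it coincides with a single
    terminal strong component; the network flag requires this of every
    class.  ``single_terminal`` is the weaker condition (exactly one
    terminal component per linkage class) under which the kernel of the
    kinetic matrix still has dimension ``l``.
    """
    g = _digraph(net)
    cond = nx.condensation(g)
    terminal_sccs = [
        tuple(sorted(cond.nodes[node]["members"]))
        for node in cond.nodes
        if cond.out_degree(node) == 0
    ]
    classes = linkage_classes(net)
    per_class: list[tuple[tuple[int, ...], ...]] = []
    for cls in classes:
        members = set(cls)
        terms = sorted(t for t in terminal_sccs if set(t) <= members)
        per_class.append(tuple(terms))
    weak = all(
        len(terms) == 1 and set(terms[0]) == set(cls)
        for cls, terms in zip(classes, per_class)
    )
    single = all(len(terms) == 1 for terms in per_class)
    return tuple(per_class), weak, single


# ---------------------------------------------------------------------------
# Stoichiometry and conservation laws
# ---------------------------------------------------------------------------

def _fix_column_signs(M: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-|entry| (first on ties
    to machine precision) is positive — makes SVD bases reproducible."""
    M = M.copy()
    for j in range(M.shape[1]):
        col = M[:, j]
        mags = np.abs(col)
        top = mags.max()
        lead = int(np.flatnonzero(mags >= top * (1 - 1e-12))[0])
        if col[lead] < 0:
            M[:, j] = -col
    return M


def stoichiometry(
    net: ReactionNetwork, rank_rtol: float = RANK_RTOL
) -> tuple[np.ndarray, int, np.ndarray]:
    """Stoichiometric subspace basis, its dimension and the conservation basis.

    Returns ``(stoich_basis, s, B)`` where ``stoich_basis`` is an m x s
    orthonormal basis of ``S = span{y_j - y_i}`` over all reactions,
    ``s`` is the numerical rank (SVD, relative threshold ``rank_rtol``),
    and ``B`` is an m x (m-s) basis of the orthogonal complement:
    mutually orthogonal columns, each scaled so its largest-magnitude
    entry is exactly +1 (conserved totals such as ``c_B + c_C`` then
    read off directly, and the convention is reproducible across runs).
    ``B`` is empty when ``s = m`` (the reaction polyhedron is then the
    whole positive orthant).
    """
    Y = net.Y
    R = np.column_stack([Y[:, j] - Y[:, i] for i, j, _ in net.reactions])
    U, sv, _ = np.linalg.svd(R, full_matrices=True)
    tol = rank_rtol * (sv[0] if sv.size else 0.0)
    s = int(np.sum(sv > tol))
    basis = _fix_column_signs(U[:, :s])
    B = U[:, s:].copy()
    for j in range(B.shape[1]):
        col = B[:, j]
        mags = np.abs(col)
        lead = int(np.flatnonzero(mags >= mags.max() * (1 - 1e-12))[0])
        B[:, j] = col / col[lead]
    return basis, s, B


def structural_report(
    net: ReactionNetwork, rank_rtol: float = RANK_RTOL
) -> StructuralReport:
    """Assemble the full structural report.

    Deficiency ``delta = n - l - s``; the layout class compares the
    deficiency with the equilibrium-manifold dimension ``m - s``; the
    deficiency-zero theorem excludes multistationarity whenever
    ``delta = 0`` and the network is weakly reversible.
    """
    classes = linkage_classes(net)
    terms, weak, single = terminal_strong_classes(net)
    stoich_basis, s, B = stoichiometry(net, rank_rtol)
    n, m, l = net.n_complexes, net.n_species, len(classes)
    delta = n - l - s
    if delta < 0:  # impossible for valid networks; guards numerics
        raise NetworkError(f"negative deficiency {delta}: rank computation failed")
    manifold_dim = m - s
    diff = delta - manifold_dim
    layout = "proper" if diff == 0 else ("overdimensioned" if diff > 0 else "underdimensioned")
    omega_ind = np.zeros((l, n))
    for k, cls in enumerate(classes):
        omega_ind[k, list(cls)] = 1.0
    return StructuralReport(
        net=net,
        linkage_classes=classes,
        terminal_strong_classes=terms,
        weakly_reversible=weak,
        single_terminal_per_class=single,
        Y=net.Y,
        stoich_basis=stoich_basis,
        s=s,
        B=B,
        omega_indicators=omega_ind,
        deficiency=delta,
        manifold_dim=manifold_dim,
        layout_class=layout,
        multistationarity_excluded=(delta == 0 and weak),
    )
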
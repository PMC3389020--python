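"""Reference networks and seeded random network generators.

The Edelstein autocatalytic network (A <-> 2A, B <-> C <-> A + B) is
the canonical bistable test case: three species, five complexes, two
linkage classes, deficiency one.  With the standard rate-constant set
{8.5, 1, 0.2, 1, 1, 1} it exhibits three positive equilibria in a range
of the conserved total c_B + c_C, bounded by two saddle-node points.

Note on the rate assignment: the mapping of the six published constants
onto the six reaction steps is ambiguous in secondary sources.  The
default here places 0.2 on B -> C, which is the placement class that
produces the three-equilibria / two-fold behaviour; all placements in
that class yield the identical equilibrium set in (c_A, Gamma).  Pass
``rates=`` to override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkError, ReactionNetwork, network_from_reactions

__all__ = [
    "FixtureSpec",
    "edelstein",
    "chain_deficiency_zero",
    "random_weakly_reversible",
    "random_deficiency_zero",
]

DEFAULT_SEED = 20120703

#: default Edelstein rate constants, in the step order
#: (A->2A, 2A->A, B->C, C->B, C->A+B, A+B->C)
EDELSTEIN_RATES = (8.5, 1.0, 0.2, 1.0, 1.0, 1.0)


def edelstein(rates: tuple[float, ...] = EDELSTEIN_RATES) -> tuple[ReactionNetwork, np.ndarray]:
    """The Edelstein network and its rate-constant vector.

    Structure: n = 5 complexes (A, B, C, 2A, A+B), l = 2 linkage
    classes, s = 2, deficiency 1, weakly reversible.
    """
    k = tuple(float(x) for x in rates)
    if len(k) != 6:
        raise NetworkError("expected 6 rate constants")
    net = network_from_reactions(
        ["A", "B", "C"],
        [
            ({"A": 1}, {"A": 2}, k[0]),
            ({"A": 2}, {"A": 1}, k[1]),
            ({"B": 1}, {"C": 1}, k[2]),
            ({"C": 1}, {"B": 1}, k[3]),
            ({"C": 1}, {"A": 1, "B": 1}, k[4]),
            ({"A": 1, "B": 1}, {"C": 1}, k[5]),
        ],
    )
    return net, net.K


def chain_deficiency_zero(length: int = 3) -> tuple[ReactionNetwork, np.ndarray]:
    """Reversible chain A1 <-> A2 <-> ... <-> A_len with unit constants.

    A textbook deficiency-zero weakly reversible network: a unique
    stable positive equilibrium in every compatibility class.
    """
    if length < 2:
        raise NetworkError("chain length must be >= 2")
    species = [f"A{i + 1}" for i in range(length)]
    reactions = []
    for i in range(length - 1):
        reactions.append(({species[i]: 1}, {species[i + 1]: 1}, 1.0))
        reactions.append(({species[i + 1]: 1}, {species[i]: 1}, 1.0))
    net = network_from_reactions(species, reactions)
    return net, net.K


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the seeded random weakly reversible generator."""

    n_species: int = 3
    n_complexes: int = 4
    n_classes: int = 1
    extra_edges: int = 0
    k_log10_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = DEFAULT_SEED


def random_weakly_reversible(spec: FixtureSpec) -> tuple[ReactionNetwork, np.ndarray]:
    """Seeded random weakly reversible network.

    Samples distinct complexes over the species, partitions them into
    linkage classes (each of size >= 2), and connects every class with
    a random spanning tree of reversible edges plus ``extra_edges``
    additional reversible edges.  Weak reversibility holds by
    construction; rate constants are log-uniform over
    ``k_log10_range``.  Deterministic per seed.
    """
    if spec.n_classes * 2 > spec.n_complexes:
        raise NetworkError(
            "infeasible fixture: each linkage class needs >= 2 complexes")
    if spec.n_species < 1:
        raise NetworkError("need at least one species")
    rng = np.random.default_rng(spec.seed)

    complexes: list[tuple[int, ...]] = []
    seen = set()
    attempts = 0
    while len(complexes) < spec.n_complexes:
        attempts += 1
        if attempts > 10000:
            raise NetworkError("cannot sample enough distinct complexes")
        vec = tuple(int(x) for x in rng.integers(0, 3, size=spec.n_species))
        if sum(vec) == 0 or vec in seen:
            continue
        seen.add(vec)
        complexes.append(vec)

    order = rng.permutation(spec.n_complexes)
    sizes = np.full(spec.n_classes, 2)
    for _ in range(spec.n_complexes - 2 * spec.n_classes):
        sizes[rng.integers(spec.n_classes)] += 1
    groups: list[list[int]] = []
    pos = 0
    for size in sizes:
        groups.append([int(order[pos + i]) for i in range(size)])
        pos += size

    species = [f"X{i + 1}" for i in range(spec.n_species)]
    pairs: set[tuple[int, int]] = set()
    for group in groups:
        for i in range(1, len(group)):
            j = int(rng.integers(i))
            pairs.add((group[j], group[i]))
        for _ in range(spec.extra_edges):
            if len(group) < 2:
                break
            a, b = rng.choice(len(group), size=2, replace=False)
            u, v = group[int(a)], group[int(b)]
            if (u, v) not in pairs and (v, u) not in pairs:
                pairs.add((u, v))

    def as_map(ci: int) -> dict[str, int]:
        return {s: c for s, c in zip(species, complexes[ci]) if c}

    reactions = []
    for u, v in sorted(pairs):
        k_fwd = float(10.0 ** rng.uniform(*spec.k_log10_range))
        k_rev = float(10.0 ** rng.uniform(*spec.k_log10_range))
        reactions.append((as_map(u), as_map(v), k_fwd))
        reactions.append((as_map(v), as_map(u), k_rev))
    net = network_from_reactions(species, reactions)
    return net, net.K


def random_deficiency_zero(count: int, seed: int = DEFAULT_SEED):
    """Yield ``count`` random weakly reversible deficiency-zero networks.

    Scans the seeded generator and keeps only networks whose structural
    report gives ``delta = 0`` (rejection sampling; deterministic for a
    given ``seed``).  Yields ``(net, K, report)`` triples.
    """
    from .network import structural_report

    produced = 0
    offset = 0
    while produced < count:
        spec = FixtureSpec(
            n_species=2 + offset % 3,
            n_complexes=4 + offset % 3,
            n_classes=1 + offset % 2,
            extra_edges=0,
            seed=seed + offset,
        )
        offset += 1
        try:
            net, K = random_weakly_reversible(spec)
        except NetworkError:
            continue
        rep = structural_report(net)
        if rep.deficiency == 0 and rep.weakly_reversible:
            produced += 1
            yield net, K, rep
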
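"""Shared fixtures and closed-form oracles for the Edelstein network.

The Edelstein autocatalytic network (A <-> 2A, B <-> C <-> A+B) admits
closed-form elimination of its equilibrium manifold: with the standard
rate constants, solving the three residual equations for the branch
parametrized by A = c_A gives

    c_B(A)   = 2 A (8.5 - A) / (A - 0.2)
    c_C(A)   = 0.2 c_B(A) + A (8.5 - A)
    alpha(A) = A^2 - 8.5 A
    Gamma(A) = c_B + c_C = A (8.5 - A)(A + 2.2) / (A - 0.2)

These expressions are derived independently of the package (pencil and
paper / rational arithmetic) and serve as the oracle for curve tracing,
fold detection and equilibrium counting.  Stationary points of Gamma
are the roots of 2 A^3 - 6.9 A^2 + 2.52 A + 3.74 = 0.
"""

import numpy as np
import pytest

from crnstab import build_manifold, fixtures, structural_report, trace_curve

#: dGamma/dA numerator: 2 A^3 - 6.9 A^2 + 2.52 A + 3.74 = 0 at the folds
FOLD_CUBIC = (2.0, -6.9, 2.52, 3.74)


def edelstein_curve_point(A: float):
    """Closed-form (c, alpha) on the positive equilibrium branch."""
    cB = 2.0 * A * (8.5 - A) / (A - 0.2)
    cC = 0.2 * cB + A * (8.5 - A)
    alpha = A * A - 8.5 * A
    return np.array([A, cB, cC]), np.array([alpha])


def edelstein_gamma(A: float) -> float:
    return A * (8.5 - A) * (A + 2.2) / (A - 0.2)


def fold_roots():
    """Positive roots of the fold cubic, ascending (the two saddle-nodes)."""
    roots = np.roots(FOLD_CUBIC)
    roots = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-12 and r.real > 0.2)
    return roots


@pytest.fixture(scope="session")
def edelstein_net():
    return fixtures.edelstein()


@pytest.fixture(scope="session")
def edelstein_model(edelstein_net):
    net, K = edelstein_net
    return build_manifold(net, K)


@pytest.fixture(scope="session")
def edelstein_curve(edelstein_model):
    return trace_curve(edelstein_model, param="A", prange=(0.25, 8.4), step=0.02)


@pytest.fixture(scope="session")
def chain3():
    return fixtures.chain_deficiency_zero(3)


@pytest.fixture(scope="session")
def chain3_report(chain3):
    net, _ = chain3
    return structural_report(net)
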
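"""Deterministic mass-action fixed point of the fission-fusion model.

Setting the net flux of both reversible reactions to zero gives, for the
default ``"squared"`` convention,

    X2 = C1 * X1**2,        X3 = C2 * X1 * X2,

subject to tip conservation ``X1 + 2*X2 + 3*X3 = 2*N``.  Substituting
reduces the fixed point to a single monotone cubic in ``X1`` on
``[0, 2N]``, solved by bracketed root finding; the non-negative root is
unique.  Every propensity convention of the stochastic simulator has its
mirrored balance relation here, keyed by the same name, so the oracle
and the simulator always describe the same model.

The fixed point serves two purposes: an independent consistency oracle
for the stochastic ensemble means (they must agree within Monte-Carlo
error at large ``N``), and a fast initializer/sanity check for
phase-space fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .simulate import CONVENTIONS, DEFAULT_CONVENTION

__all__ = ["MeanFieldSolution", "steady_state", "mean_degree_meanfield"]


@dataclass
class MeanFieldSolution:
    """Continuous steady-state node counts and the solver residual."""

    X1: float
    X2: float
    X3: float
    N: int
    convention: str
    residual: float

    @property
    def n_nodes(self) -> float:
        return self.X1 + self.X2 + self.X3

    def fractions(self) -> tuple:
        m = self.n_nodes
        return self.X1 / m, self.X2 / m, self.X3 / m


def _balance(C1: float, C2: float, convention: str):
    """X2(X1) and X3(X1, X2) from the per-reaction flux balance."""
    if convention == "squared":
        def x2(x1):
            return C1 * x1 * x1
    elif convention in ("pairwise", "triple-fission"):
        def x2(x1):
            return 0.5 * C1 * x1 * max(x1 - 1.0, 0.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    c2_eff = C2 / 3.0 if convention == "triple-fission" else C2

    def x3(x1, x2v):
        return c2_eff * x1 * x2v

    return x2, x3


def steady_state(C1: float, C2: float, N: int,
                 convention: str = DEFAULT_CONVENTION) -> MeanFieldSolution:
    """Unique non-negative fixed point of the rate equations.

    ``C1 = C2 = 0`` gives the fully fragmented state ``X1 = 2N``; with
    ``C2 = 0`` the problem closes to a quadratic in ``X1``, and in
    general to a cubic whose conserved-mass function is strictly
    increasing in ``X1``, so bisection on ``[0, 2N]`` cannot miss.
    """
    if C1 < 0 or C2 < 0:
        raise ValueError("C1 and C2 must be non-negative")
    if N < 1:
        raise ValueError("need at least one edge")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    two_n = 2.0 * N
    x2_of, x3_of = _balance(C1, C2, convention)

    def mass(x1):
        x2 = x2_of(x1)
        return x1 + 2.0 * x2 + 3.0 * x3_of(x1, x2) - two_n

    if C1 == 0.0:  # no X2 can form, hence no X3 either
        x1 = two_n
    else:
        x1 = brentq(mass, 0.0, two_n, xtol=1e-12 * max(two_n, 1.0), rtol=1e-15)
    x2 = x2_of(x1)
    x3 = x3_of(x1, x2)
    return MeanFieldSolution(X1=x1, X2=x2, X3=x3, N=N, convention=convention,
                             residual=abs(x1 + 2 * x2 + 3 * x3 - two_n))


def mean_degree_meanfield(solution: MeanFieldSolution) -> float:
    """``<k> = 2N / (X1 + X2 + X3)``: tips per node at the fixed point."""
    return 2.0 * solution.N / solution.n_nodes
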
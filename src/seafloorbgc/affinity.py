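"""Minimum-affinity, diffusion-limited organic-oxidation model.

A single dissolved metabolite (bicarbonate, the dominant DIC species) is
produced at a rate that shuts off as its concentration approaches the level
at which the catabolic reaction no longer yields harvestable energy:

    P(z) = P_max * (1 - c(z) / c_a_min),
    0 = D * c''(z) + P(z),   c(0) = c_top,  c'(z) -> 0 at depth.

The solution decays exponentially toward ``c_a_min`` with e-folding length
L = sqrt(D * c_a_min / P_max), so the metabolic rate itself decays as
exp(-z/L). A finite-difference boundary-value solver is provided as an
independent numerical oracle, and a Gibbs-energy-per-electron check decides
whether a reaction is biologically harvestable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "AffinityModelParams",
    "AffinityCheck",
    "analytic_concentration",
    "analytic_rate",
    "efolding_length",
    "fd_steady_state",
    "is_harvestable",
]


@dataclass(frozen=True)
class AffinityModelParams:
    """Parameters of the affinity-limited production model.

    p_max : mol m^-3 yr^-1
        Maximum production rate, reached where the metabolite is absent.
    c_a_min : mol m^-3
        Metabolite concentration at which the reaction affinity falls to
        the biological minimum and production stops.
    diffusivity : m^2 yr^-1
    c_top : mol m^-3
        Fixed concentration at the top boundary (z = 0).
    """

    p_max: float
    c_a_min: float
    diffusivity: float
    c_top: float = 0.0

    def __post_init__(self) -> None:
        if self.p_max <= 0:
            raise ValueError("p_max must be positive")
        if self.c_a_min <= 0:
            raise ValueError("c_a_min must be positive")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if not (0.0 <= self.c_top <= self.c_a_min):
            raise ValueError("c_top must lie in [0, c_a_min]")


@dataclass(frozen=True)
class AffinityCheck:
    """Reaction energetics for the harvestability criterion."""

    delta_g: float  # kJ per mol reaction (negative when exergonic)
    electrons_transferred: float  # mol e- per mol reaction
    a_min_low: float = 2.0  # kJ per mol e-
    a_min_high: float = 5.0

    def __post_init__(self) -> None:
        if self.electrons_transferred <= 0:
            raise ValueError("electrons transferred must be positive")
        if not (0 < self.a_min_low <= self.a_min_high):
            raise ValueError("need 0 < a_min_low <= a_min_high")


def efolding_length(params: AffinityModelParams) -> float:
    """Decay length L = sqrt(D * c_a_min / p_max), meters."""
    return math.sqrt(params.diffusivity * params.c_a_min / params.p_max)


def analytic_concentration(params: AffinityModelParams, z) -> np.ndarray | float:
    """Closed-form concentration c(z) = c_a_min + (c_top - c_a_min) e^{-z/L}."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    length = efolding_length(params)
    c = params.c_a_min + (params.c_top - params.c_a_min) * np.exp(-z / length)
    return float(c) if c.shape == () else c


def analytic_rate(params: AffinityModelParams, z) -> np.ndarray | float:
    """Production rate P(z) = p_max (1 - c(z)/c_a_min), decaying as e^{-z/L}."""
    c = np.asarray(analytic_concentration(params, z))
    p = params.p_max * (1.0 - c / params.c_a_min)
    return float(p) if p.shape == () else p


def fd_steady_state(
    params: AffinityModelParams, depth_max: float, n_nodes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite-difference solution of the boundary-value problem.

    Independent numerical oracle for the closed form: solves
    D c'' + p_max (1 - c/c_a_min) = 0 with c(0) = c_top and zero gradient
    at ``depth_max``. Returns (depths, concentration, rate).
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    if depth_max <= 0:
        raise ValueError("depth_max must be positive")
    z = np.linspace(0.0, depth_max, n_nodes)
    h = z[1] - z[0]
    d = params.diffusivity
    k = params.p_max / params.c_a_min  # linear sink coefficient

    n = n_nodes
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    ab[1, 0] = 1.0
    rhs[0] = params.c_top
    idx = np.arange(1, n - 1)
    # D (c_{i-1} - 2 c_i + c_{i+1})/h^2 - k c_i = -p_max
    ab[0, idx + 1] = d / h**2
    ab[1, idx] = -2.0 * d / h**2 - k
    ab[2, idx - 1] = d / h**2
    rhs[idx] = -params.p_max
    # zero-gradient bottom via ghost node: 2D(c_{n-2} - c_{n-1})/h^2 - k c_{n-1} = -p_max
    ab[1, n - 1] = -2.0 * d / h**2 - k
    ab[2, n - 2] = 2.0 * d / h**2
    rhs[n - 1] = -params.p_max

    conc = solve_banded((1, 1), ab, rhs)
    rate = params.p_max * (1.0 - conc / params.c_a_min)
    return z, conc, rate


def is_harvestable(check: AffinityCheck) -> dict:
    """Decide whether a reaction's energy yield is biologically harvestable.

    The affinity A = -delta_g per electron must equal or exceed the minimum
    threshold (boundary inclusive). Both ends of the 2-5 kJ (mol e-)^-1
    range are reported, with the margin relative to the low threshold.
    """
    affinity = -check.delta_g
    per_electron = affinity / check.electrons_transferred
    return {
        "affinity_kj": affinity,
        "per_electron_kj": per_electron,
        "harvestable_at_low": per_electron >= check.a_min_low,
        "harvestable_at_high": per_electron >= check.a_min_high,
        "margin_at_low_kj": per_electron - check.a_min_low,
    }
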
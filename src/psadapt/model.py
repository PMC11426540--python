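"""Lotka-Volterra competition model of mCRPC under abiraterone.

Three cancer cell types compete for a shared niche: testosterone-dependent
cells (T+), testosterone-producing cells (TP) and testosterone-independent
cells (T-).  Each type i grows logistically with competition,

    dx_i/dt = r_i * x_i * (1 - sum_j a_ij * x_j / K_i),

where ``A = (a_ij)`` is the competition matrix.  Abiraterone blocks
testosterone synthesis by the TP cells, modelled as a collapse of the TP
carrying capacity while the drug is on.  T+ cells survive only on the
testosterone the TP cells produce, so their carrying capacity is coupled to
the TP density, ``K_T+ = mu * x_TP``; treatment also halves the coupling
coefficient ``mu``.  T- cells ignore the drug entirely.

Tumor burden is observed through serum PSA.  Cell types may secrete PSA at
different per-cell rates, captured by a convex weighting

    PSA(t) = alpha * x_T+(t) + beta * x_TP(t) + (1 - alpha - beta) * x_T-(t),

with ``0 <= alpha <= 1`` and ``0 <= beta <= 1 - alpha``.

This module is pure computation: the state containers, the vector field, the
PSA read-out and the untreated-equilibrium solve used to classify patients.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "K_FLOOR",
    "Populations",
    "ModelParams",
    "PSAWeights",
    "InvalidParameterError",
    "InvalidWeightsError",
    "NoFeasibleEquilibriumError",
    "carrying_capacities",
    "rhs",
    "make_rhs",
    "psa",
    "untreated_equilibrium",
]

#: Lower bound applied to every carrying capacity inside the vector field.
#: K_T+ = mu * x_TP vanishes as the TP population collapses, which would make
#: x/K singular; flooring K keeps the vector field finite and turns the
#: degenerate regime into a steep (biologically sensible) decline of T+.
K_FLOOR = 1e-9


class InvalidParameterError(ValueError):
    """A growth rate, carrying capacity or competition entry is out of range."""


class InvalidWeightsError(ValueError):
    """PSA production weights leave the feasible simplex."""


class NoFeasibleEquilibriumError(RuntimeError):
    """No equilibrium support yields non-negative populations."""


@dataclass(frozen=True)
class Populations:
    """Cell counts of the three competing types (T+, TP, T-)."""

    x_tplus: float
    x_tp: float
    x_tminus: float

    def __post_init__(self) -> None:
        for name in ("x_tplus", "x_tp", "x_tminus"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_tplus, self.x_tp, self.x_tminus], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "Populations":
        return cls(float(x[0]), float(x[1]), float(x[2]))

    @property
    def total(self) -> float:
        return self.x_tplus + self.x_tp + self.x_tminus


@dataclass(frozen=True)
class ModelParams:
    """Growth rates, carrying capacities and competition structure.

    Growth rates derive from doubling times of representative cell lines
    (LNCaP for T+, H295R for TP, PC-3 for T-); time is measured in days.
    ``K_tp_on`` is the collapsed TP carrying capacity while abiraterone is
    administered; ``mu_off``/``mu_on`` couple the T+ capacity to the TP
    density off/on treatment.
    """

    A: np.ndarray
    r_tplus: float = 0.0027726
    r_tp: float = 0.0034657
    r_tminus: float = 0.0066542
    K_tp_off: float = 10000.0
    K_tp_on: float = 100.0
    K_tminus: float = 10000.0
    mu_off: float = 1.5
    mu_on: float = 0.5

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape != (3, 3):
            raise InvalidParameterError(f"competition matrix must be 3x3, got {A.shape}")
        object.__setattr__(self, "A", A)
        for name in ("r_tplus", "r_tp", "r_tminus"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"growth rate {name} must be > 0")
        for name in ("K_tp_off", "K_tp_on", "K_tminus"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"carrying capacity {name} must be > 0")
        if not np.all(np.diag(A) == 1.0):
            raise InvalidParameterError("diagonal of competition matrix must equal 1")
        off = A[~np.eye(3, dtype=bool)]
        if np.any(off <= 0) or np.any(off > 1):
            raise InvalidParameterError("off-diagonal competition entries must lie in (0, 1]")

    @property
    def growth_rates(self) -> np.ndarray:
        return np.array([self.r_tplus, self.r_tp, self.r_tminus])


@dataclass(frozen=True)
class PSAWeights:
    """Per-cell PSA production weights (alpha for T+, beta for TP).

    The T- weight is implied: gamma = 1 - alpha - beta.  Feasibility requires
    0 <= alpha <= 1 and 0 <= beta <= 1 - alpha, so all three weights form a
    convex combination.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidWeightsError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0 - self.alpha + 1e-12):
            raise InvalidWeightsError(
                f"beta must be in [0, 1 - alpha], got beta={self.beta}, alpha={self.alpha}"
            )

    @property
    def gamma(self) -> float:
        """Implied T- weight."""
        return 1.0 - self.alpha - self.beta

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


def carrying_capacities(
    pops: Populations, params: ModelParams, treatment_on: bool
) -> tuple[float, float, float]:
    """Instantaneous carrying capacities (K_T+, K_TP, K_T-).

    K_TP switches between its off- and on-treatment values; K_T- is constant;
    K_T+ tracks the TP density linearly (K_T+ = mu * x_TP).  A degenerate
    K_T+ = 0 is legal output — the vector field floors it at `K_FLOOR`.
    """
    mu = params.mu_on if treatment_on else params.mu_off
    k_tp = params.K_tp_on if treatment_on else params.K_tp_off
    return (mu * pops.x_tp, k_tp, params.K_tminus)


def make_rhs(params: ModelParams, treatment_on: bool) -> Callable[[float, np.ndarray], np.ndarray]:
    """Closure form of the vector field for ODE solvers (t, x) -> dx/dt."""
    r = params.growth_rates
    A = params.A
    mu = params.mu_on if treatment_on else params.mu_off
    k_tp = params.K_tp_on if treatment_on else params.K_tp_off
    k_tm = params.K_tminus

    def f(t: float, x: np.ndarray) -> np.ndarray:
        K = np.array([max(mu * x[1], K_FLOOR), k_tp, k_tm])
        return r * x * (1.0 - (A @ x) / K)

    return f


def rhs(pops: Populations, params: ModelParams, treatment_on: bool) -> np.ndarray:
    """Instantaneous rate of change of the three populations (cells/day)."""
    return make_rhs(params, treatment_on)(0.0, pops.as_array())


def psa(pops: Populations, w: PSAWeights) -> float:
    """Weighted PSA read-out alpha*x_T+ + beta*x_TP + (1-alpha-beta)*x_T-.

    Lies between the smallest and largest population (convex combination).
    """
    return w.alpha * pops.x_tplus + w.beta * pops.x_tp + w.gamma * pops.x_tminus


# ---------------------------------------------------------------------------
# Untreated equilibrium and classification support
# ---------------------------------------------------------------------------

_SUPPORT_LABELS = ("T+", "TP", "T-")


def _equilibrium_candidate(
    support: tuple[int, ...], A: np.ndarray, mu_off: float, scale_K: float
) -> np.ndarray | None:
    """Solve the equilibrium system restricted to a support set.

    Active types satisfy sum_j a_ij x_j = K_i with K_TP = K_T- = scale_K and
    K_T+ = mu_off * x_TP (linear in the state, so the whole system stays
    linear).  Returns None for singular systems.
    """
    idx = list(support)
    M = np.zeros((len(idx), len(idx)))
    b = np.zeros(len(idx))
    for row, i in enumerate(idx):
        for col, j in enumerate(idx):
            M[row, col] = A[i, j]
        if i == 0:  # T+: move mu*x_TP to the left-hand side
            if 1 in idx:
                M[row, idx.index(1)] -= mu_off
            b[row] = 0.0
        else:
            b[row] = scale_K
    try:
        sol = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        return None
    x = np.zeros(3)
    x[idx] = sol
    return x


def _jacobian(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Central-difference Jacobian of the off-treatment vector field."""
    f = make_rhs(params, treatment_on=False)
    J = np.zeros((3, 3))
    for j in range(3):
        h = 1e-6 * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (f(0.0, xp) - f(0.0, xm)) / (2 * h)
    return J


def untreated_equilibrium(
    params: ModelParams, scale_K: float = 1000.0
) -> tuple[Populations, tuple[str, ...]]:
    """Stable coexistence equilibrium of the drug-free system.

    Both fixed carrying capacities (TP and T-) are set to ``scale_K`` for the
    solve; because the system is linear in the state, the equilibrium scales
    linearly in ``scale_K``.  All seven non-empty supports are enumerated; a
    candidate is kept if every component is >= -1e-9 (then clamped to zero)
    and the Jacobian of the full system at the candidate has no eigenvalue
    with real part above tolerance.  Among stable candidates the largest
    support wins (deterministic tie-break).

    Returns the equilibrium populations and the labels of the surviving types.

    Raises
    ------
    NoFeasibleEquilibriumError
        If no support yields a non-negative candidate.
    """
    if scale_K <= 0:
        raise InvalidParameterError(f"scale_K must be > 0, got {scale_K}")
    scaled = replace(params, K_tp_off=scale_K, K_tminus=scale_K)

    supports = sorted(
        (s for n in (3, 2, 1) for s in itertools.combinations(range(3), n)),
        key=lambda s: (-len(s), s),
    )
    feasible: list[tuple[tuple[int, ...], np.ndarray]] = []
    for support in supports:
        x = _equilibrium_candidate(support, params.A, params.mu_off, scale_K)
        if x is None or np.any(x < -1e-9):
            continue
        x = np.clip(x, 0.0, None)
        feasible.append((support, x))
        eig = np.linalg.eigvals(_jacobian(x, scaled))
        if np.all(eig.real < 1e-8):
            pops = Populations.from_array(x)
            return pops, tuple(_SUPPORT_LABELS[i] for i in support)
    if not feasible:
        raise NoFeasibleEquilibriumError(
            "no equilibrium support yields non-negative populations"
        )
    # No strictly stable candidate (degenerate spectra): fall back to the
    # largest feasible support so classification remains total.
    support, x = feasible[0]
    return Populations.from_array(x), tuple(_SUPPORT_LABELS[i] for i in support)
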
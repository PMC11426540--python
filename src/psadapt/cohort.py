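"""Virtual patient generation and response-category classification.

The study population is parameterised by the competition matrix: each of the
six inter-type coefficients takes a value from the discrete set
{0.4, 0.5, 0.6, 0.7, 0.8, 0.9}.  A virtual patient is a draw of such a
matrix plus initial conditions tied to the untreated equilibrium (therapy
starts when the tumor has grown to a fixed fraction of its equilibrium
burden; the representative presets correspond to one tenth).

Patients are classified by the frequency f of the resistant T- type at the
untreated equilibrium: best responders have f ~ 0 (T- competitively
excluded), non-responders f >= 20%, responders anything in between.

`synthesize_psa_series` additionally turns a simulated continuous PSA trace
into discrete noisy measurements, for exercising protocol logic against
sampled rather than continuous observations.  The underlying model is
deterministic, so noise is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, Populations, untreated_equilibrium
from .simulate import SimulationResult

__all__ = [
    "OFFDIAG_VALUES",
    "BEST_RESPONDER_CUTOFF",
    "NON_RESPONDER_CUTOFF",
    "VirtualPatient",
    "sample_competition_matrix",
    "classify_patient",
    "generate_cohort",
    "cohort_frame",
    "synthesize_psa_series",
]

#: Admissible inter-type competition coefficients.
OFFDIAG_VALUES = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

#: Equilibrium T- frequency below which T- counts as absent (best responder).
BEST_RESPONDER_CUTOFF = 1e-6
#: Equilibrium T- frequency at or above which a patient is a non-responder.
NON_RESPONDER_CUTOFF = 0.20

_OFFDIAG_IDX = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


@dataclass(frozen=True)
class VirtualPatient:
    A: np.ndarray
    init: Populations
    category: str
    equilibrium_tminus_fraction: float
    seed_info: str


def sample_competition_matrix(rng: np.random.Generator) -> np.ndarray:
    """Draw a competition matrix: unit diagonal, six independent off-diagonals
    uniform on the admissible value set."""
    A = np.eye(3)
    draws = rng.choice(OFFDIAG_VALUES, size=6)
    for (i, j), v in zip(_OFFDIAG_IDX, draws):
        A[i, j] = v
    return A


def classify_patient(
    A: np.ndarray, params: ModelParams | None = None, scale_K: float = 1000.0
) -> tuple[str, float]:
    """Response category and equilibrium T- frequency for a competition matrix.

    The untreated equilibrium frequency f = x_T- / (x_T+ + x_TP + x_T-) is
    scale-free in the carrying capacity, so any positive ``scale_K`` gives
    the same classification.
    """
    if params is None:
        params = ModelParams(A=A)
    eq, _ = untreated_equilibrium(params, scale_K=scale_K)
    f = eq.x_tminus / eq.total if eq.total > 0 else 0.0
    if f < BEST_RESPONDER_CUTOFF:
        return "best_responder", f
    if f >= NON_RESPONDER_CUTOFF:
        return "non_responder", f
    return "responder", f


def generate_cohort(
    n: int,
    seed: int,
    init_fraction: float = 0.1,
    scale_K: float = 10000.0,
) -> list[VirtualPatient]:
    """Generate ``n`` virtual patients.

    Each patient gets a sampled competition matrix, is classified by the
    untreated equilibrium at ``scale_K``, and starts therapy at
    ``init_fraction`` of that equilibrium (default one tenth, matching the
    representative presets).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 < init_fraction <= 1):
        raise ValueError(f"init_fraction must be in (0, 1], got {init_fraction}")
    rng = np.random.default_rng(seed)
    patients = []
    for k in range(n):
        A = sample_competition_matrix(rng)
        params = ModelParams(A=A)
        eq, _ = untreated_equilibrium(params, scale_K=scale_K)
        category, f = classify_patient(A, params, scale_K=scale_K)
        init = Populations.from_array(init_fraction * eq.as_array())
        patients.append(
            VirtualPatient(
                A=A,
                init=init,
                category=category,
                equilibrium_tminus_fraction=f,
                seed_info=f"seed={seed},index={k}",
            )
        )
    return patients


def cohort_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    """Flat table of a cohort, one row per patient."""
    rows = []
    for pid, p in enumerate(patients):
        rows.append(
            {
                "patient_id": pid,
                "a12": p.A[0, 1],
                "a13": p.A[0, 2],
                "a21": p.A[1, 0],
                "a23": p.A[1, 2],
                "a31": p.A[2, 0],
                "a32": p.A[2, 1],
                "category": p.category,
                "eq_tminus_fraction": p.equilibrium_tminus_fraction,
                "init_tplus": p.init.x_tplus,
                "init_tp": p.init.x_tp,
                "init_tminus": p.init.x_tminus,
                "seed": p.seed_info,
            }
        )
    return pd.DataFrame(rows)


def synthesize_psa_series(
    result: SimulationResult,
    sampling_interval: float,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Discrete PSA measurements from a simulated trajectory.

    Samples the model PSA on a regular grid starting at t = 0 and applies
    multiplicative lognormal noise with unit mean and the given coefficient
    of variation.  ``noise_cv = 0`` returns the exact model PSA; an interval
    longer than the simulated span yields the single t = 0 sample.

    Returns an array of shape (n, 2) with columns (time, observed PSA).
    """
    if sampling_interval <= 0:
        raise ValueError(f"sampling_interval must be > 0, got {sampling_interval}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    end = float(result.times[-1])
    grid = np.arange(0.0, end, sampling_interval)
    if len(grid) == 0:
        grid = np.array([0.0])
    values = np.interp(grid, result.times, result.psa_trace)
    if noise_cv > 0:
        if rng is None:
            raise ValueError("rng is required when noise_cv > 0")
        # lognormal with E[factor] = 1 and CV = noise_cv
        sigma2 = np.log1p(noise_cv**2)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=len(grid))
        values = values * factors
    return np.column_stack([grid, values])
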
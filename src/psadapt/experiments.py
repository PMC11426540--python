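"""Headline analyses: representative patients, protocol comparison, simplex scan.

Three representative virtual patients span the clinical response spectrum,
distinguished by their competition matrix and hence by the frequency of the
resistant T- type at the untreated equilibrium:

* best responder — T- is competitively excluded (equilibrium frequency 0),
* responder — T- persists at low frequency (~3.5%),
* non-responder — T- holds a high equilibrium share (>= 20%).

Each preset carries the printed competition matrix and the initial cell
counts at therapy start (one tenth of the untreated equilibrium at the full
carrying capacity).  `compare_protocols` pits continuous maximum tolerable
dose against PSA-guided adaptive therapy for a given weighting of PSA
production; `alpha_beta_scan` sweeps the whole feasible (alpha, beta)
simplex, the input for the TCR heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, Populations, PSAWeights
from .protocols import Protocol
from .simulate import DEFAULT_HORIZON, SimulationResult, SolverOptions, run

__all__ = [
    "CATEGORIES",
    "PatientPreset",
    "ComparisonRow",
    "representative_patient",
    "preset_params",
    "compare_protocols",
    "comparison_table",
    "alpha_beta_scan",
    "TABLE_WEIGHT_SETTINGS",
]

CATEGORIES = ("best_responder", "responder", "non_responder")

# Representative competition matrices, rows/columns ordered (T+, TP, T-).
_MATRICES = {
    "best_responder": np.array(
        [[1.0, 0.7, 0.8], [0.4, 1.0, 0.5], [0.6, 0.9, 1.0]]
    ),
    "responder": np.array(
        [[1.0, 0.7, 0.8], [0.4, 1.0, 0.6], [0.5, 0.9, 1.0]]
    ),
    "non_responder": np.array(
        [[1.0, 0.7, 0.9], [0.4, 1.0, 0.6], [0.5, 0.8, 1.0]]
    ),
}

# Cell counts at therapy start (t = 0) for each category.
_INITS = {
    "best_responder": (606.06, 757.58, 1.94e-10),
    "responder": (560.36, 747.59, 47.10),
    "non_responder": (319.63, 707.76, 273.97),
}

#: The four PSA-production assumptions reported in the comparison tables:
#: only T+ produces PSA, only TP, all three equally, only T-.
TABLE_WEIGHT_SETTINGS = (
    (1.0, 0.0),
    (0.0, 1.0),
    (1.0 / 3.0, 1.0 / 3.0),
    (0.0, 0.0),
)


@dataclass(frozen=True)
class PatientPreset:
    """A representative patient: category, competition matrix, initial state."""

    category: str
    A: np.ndarray
    init: Populations


@dataclass(frozen=True)
class ComparisonRow:
    """One line of an MTD-vs-AT comparison table.

    ``tcr_at`` (and the improvements) are None when adaptive therapy is not
    applicable — the drug was never withdrawn before competitive release.
    """

    alpha: float
    beta: float
    tcr_mtd: float
    tcr_at: float | None
    at_applicable: bool

    @property
    def absolute_improvement(self) -> float | None:
        if self.tcr_at is None:
            return None
        return self.tcr_at - self.tcr_mtd

    @property
    def pct_improvement(self) -> float | None:
        if self.tcr_at is None:
            return None
        return 100.0 * (self.tcr_at - self.tcr_mtd) / self.tcr_mtd


def representative_patient(category: str) -> PatientPreset:
    """Printed competition matrix and initial conditions for a category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    return PatientPreset(
        category=category,
        A=_MATRICES[category].copy(),
        init=Populations(*_INITS[category]),
    )


def preset_params(preset: PatientPreset) -> ModelParams:
    """Default model parameters with the preset's competition matrix."""
    return ModelParams(A=preset.A)


def _run_preset(
    preset: PatientPreset,
    protocol: Protocol,
    w: PSAWeights,
    horizon: float,
    solver: SolverOptions | None,
    stop_at_tcr: bool,
) -> SimulationResult:
    return run(
        preset_params(preset),
        preset.init,
        protocol,
        w,
        horizon=horizon,
        solver=solver,
        stop_at_tcr=stop_at_tcr,
    )


def compare_protocols(
    preset: PatientPreset,
    w: PSAWeights,
    horizon: float = DEFAULT_HORIZON,
    solver: SolverOptions | None = None,
    stop_at_tcr: bool = True,
    tcr_mtd: float | None = None,
) -> ComparisonRow:
    """Run both protocols on one preset and tabulate the TCR improvement.

    The MTD time to competitive release is independent of the PSA weights
    (PSA is never consulted); callers sweeping many weights can pass a
    precomputed ``tcr_mtd`` to skip the redundant run.  By default both runs
    stop at competitive release, which fully determines the table entries.
    """
    if tcr_mtd is None:
        mtd = _run_preset(preset, Protocol.MTD, w, horizon, solver, stop_at_tcr)
        tcr_mtd = mtd.tcr
    if tcr_mtd is None:
        raise RuntimeError(
            f"no competitive release under MTD within horizon {horizon} "
            f"for preset {preset.category!r}"
        )
    at = _run_preset(preset, Protocol.AT, w, horizon, solver, stop_at_tcr)
    return ComparisonRow(
        alpha=w.alpha,
        beta=w.beta,
        tcr_mtd=tcr_mtd,
        tcr_at=at.tcr if at.at_applicable else None,
        at_applicable=at.at_applicable,
    )


def comparison_table(
    preset: PatientPreset,
    weight_settings: tuple[tuple[float, float], ...] = TABLE_WEIGHT_SETTINGS,
    horizon: float = DEFAULT_HORIZON,
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """The four-row MTD-vs-AT table for one patient category."""
    rows = []
    tcr_mtd: float | None = None
    for alpha, beta in weight_settings:
        row = compare_protocols(
            preset, PSAWeights(alpha, beta), horizon, solver, tcr_mtd=tcr_mtd
        )
        tcr_mtd = row.tcr_mtd
        rows.append(row)
    return _rows_to_frame(preset.category, rows)


def alpha_beta_scan(
    preset: PatientPreset,
    step: float = 0.05,
    horizon: float = DEFAULT_HORIZON,
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """Sweep the feasible (alpha, beta) simplex on a regular lattice.

    Grid points are the multiples of ``step`` with alpha + beta <= 1 (the
    lower-triangular heatmap lattice).  The MTD run is shared across the
    whole table since its trajectory never consults PSA.
    """
    if not (0 < step <= 0.5):
        raise ValueError(f"step must be in (0, 0.5], got {step}")
    n = int(math.floor(1.0 / step + 1e-9))
    rows: list[ComparisonRow] = []
    tcr_mtd: float | None = None
    for i in range(n + 1):
        alpha = i * step
        for j in range(n + 1 - i):
            beta = j * step
            row = compare_protocols(
                preset,
                PSAWeights(min(alpha, 1.0), min(beta, 1.0 - alpha)),
                horizon,
                solver,
                tcr_mtd=tcr_mtd,
            )
            tcr_mtd = row.tcr_mtd
            rows.append(row)
    return _rows_to_frame(preset.category, rows)


def _rows_to_frame(category: str, rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": category,
            "alpha": [r.alpha for r in rows],
            "beta": [r.beta for r in rows],
            "tcr_mtd": [r.tcr_mtd for r in rows],
            "tcr_at": [r.tcr_at for r in rows],
            "at_applicable": [r.at_applicable for r in rows],
            "abs_improvement": [r.absolute_improvement for r in rows],
            "pct_improvement": [r.pct_improvement for r in rows],
        }
    )
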
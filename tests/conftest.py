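"""Shared fixtures: printed reference tables and cached headline runs."""

from __future__ import annotations

import numpy as np
import pytest

from psadapt import representative_patient
from psadapt.experiments import comparison_table, preset_params

THIRD = 1.0 / 3.0

#: Published comparison tables: category -> {(alpha, beta): (tcr_mtd, tcr_at)}
#: with tcr_at None where adaptive therapy is not applicable.
PUBLISHED_TABLES = {
    "best_responder": {
        (1.0, 0.0): (4075, 5374),
        (0.0, 1.0): (4075, 4665),
        (THIRD, THIRD): (4075, 4596),
        (0.0, 0.0): (4075, None),
    },
    "responder": {
        (1.0, 0.0): (202, 497),
        (0.0, 1.0): (202, 499),
        (THIRD, THIRD): (202, 382),
        (0.0, 0.0): (202, None),
    },
    "non_responder": {
        (1.0, 0.0): (59, None),
        (0.0, 1.0): (59, 171),
        (THIRD, THIRD): (59, None),
        (0.0, 0.0): (59, None),
    },
}

#: Published integer percent improvements where adaptive therapy applies.
PUBLISHED_PCT = {
    "best_responder": {(1.0, 0.0): 32, (0.0, 1.0): 14, (THIRD, THIRD): 13},
    "responder": {(1.0, 0.0): 146, (0.0, 1.0): 147, (THIRD, THIRD): 89},
}

#: Cell counts at therapy start (one tenth of the untreated equilibrium).
TABLE1_INITS = {
    "best_responder": np.array([606.06, 757.58, 1.94e-10]),
    "responder": np.array([560.36, 747.59, 47.10]),
    "non_responder": np.array([319.63, 707.76, 273.97]),
}


@pytest.fixture(scope="session")
def presets():
    return {cat: representative_patient(cat) for cat in PUBLISHED_TABLES}


@pytest.fixture(scope="session")
def preset_model_params(presets):
    return {cat: preset_params(p) for cat, p in presets.items()}


@pytest.fixture(scope="session")
def comparison_tables(presets):
    """The three four-row MTD-vs-AT tables, computed once per session."""
    return {cat: comparison_table(p) for cat, p in presets.items()}
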
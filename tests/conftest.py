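"""Shared fixtures and independent oracle helpers.

The helpers here are deliberately naive (python loops, textbook formulas):
they serve as independent cross-checks of the vectorised implementations and
must stay that way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from covlink.strata import STRATUM_COLS


def make_women(rows: list[dict]) -> pd.DataFrame:
    """Build a household table from compact per-woman dicts."""
    defaults = {
        "cluster_id": "c0",
        "months_since_birth": 10,
        "anc_visits": 0,
        "first_visit_month": np.nan,
        "comp_blood_pressure": False,
        "comp_urine_sample": False,
        "comp_blood_sample": False,
        "comp_weight": False,
        "comp_height": False,
        "source_type": None,
        "source_authority": None,
        "residence": "rural",
        "weight": 1.0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"woman_id": f"w{i}", **defaults, **row}
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=["woman_id", *defaults])
    return pd.DataFrame(records)


def make_readiness(values: dict, counts: dict | None = None) -> pd.DataFrame:
    """Build a stratum readiness table from {stratum: {intervention: r}}."""
    idx = pd.MultiIndex.from_tuples(list(values.keys()), names=STRATUM_COLS)
    table = pd.DataFrame(list(values.values()), index=idx)
    table["facility_count"] = [
        (counts or {}).get(s, 1.0) for s in values.keys()
    ]
    table["n_facilities"] = 1
    return table


def weighted_mean_oracle(flags, weights) -> float:
    """Plain-python weighted proportion."""
    num = 0.0
    den = 0.0
    for f, w in zip(flags, weights):
        num += w * (1.0 if f else 0.0)
        den += w
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
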
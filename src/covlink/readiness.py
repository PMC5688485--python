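"""Facility readiness scoring and stratum-level aggregation.

A facility is *ready* to deliver an intervention when every item on that
intervention's checklist (drugs, tests, equipment) was observed available on
the day of assessment — readiness is a strict conjunction, not a graded
score. Facility-level readiness is then summarised per stratum (facility
type x managing authority x location) as the sampling-weighted proportion of
ready facilities, which is the quantity the linking estimator joins against
household care-seeking shares.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Dict, List, Mapping

import pandas as pd
import yaml

from .strata import STRATUM_COLS

logger = logging.getLogger(__name__)

Checklist = Dict[str, List[str]]


class ChecklistSchemaError(KeyError):
    """A checklist references an item absent from the facility records."""


def default_checklist() -> Checklist:
    """Load the package's default per-intervention readiness checklists."""
    with resources.files("covlink").joinpath("data/checklists.yaml").open() as fh:
        return load_checklist(fh)


def load_checklist(source) -> Checklist:
    """Load a checklist mapping from a YAML path or open file handle."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    checklist = {str(k): [str(i) for i in v] for k, v in raw.items()}
    for intervention, items in checklist.items():
        if len(items) == 0:
            raise ValueError(f"checklist for {intervention!r} has no required items")
    return checklist


def score_facility(items: Mapping[str, object], checklist: Checklist) -> Dict[str, int]:
    """Score one facility's readiness for every intervention.

    Parameters
    ----------
    items
        Mapping from item name to availability flag. A missing value
        (``None``/NaN) is treated as not available.
    checklist
        Per-intervention lists of required items.

    Returns
    -------
    dict
        ``{intervention: 0 or 1}`` — 1 iff all required items are available.

    Raises
    ------
    ChecklistSchemaError
        If a checklist names an item that does not exist in ``items`` at all
        (as opposed to being present but unavailable).
    """
    scores: Dict[str, int] = {}
    for intervention, required in checklist.items():
        ready = 1
        for item in required:
            if item not in items:
                raise ChecklistSchemaError(
                    f"checklist item {item!r} (intervention {intervention!r}) "
                    "not present in facility record"
                )
            value = items[item]
            if value is None or pd.isna(value) or not bool(value):
                ready = 0
        scores[intervention] = ready
    return scores


def score_facilities(facilities: pd.DataFrame, checklist: Checklist) -> pd.DataFrame:
    """Vectorised readiness scores, one 0/1 column per intervention."""
    out = pd.DataFrame(index=facilities.index)
    n_missing = 0
    for intervention, required in checklist.items():
        ready = pd.Series(True, index=facilities.index)
        for item in required:
            if item not in facilities.columns:
                raise ChecklistSchemaError(
                    f"checklist item {item!r} (intervention {intervention!r}) "
                    "not a column of the facility table"
                )
            col = facilities[item]
            n_missing += int(col.isna().sum())
            ready &= col.fillna(False).astype(bool)
        out[intervention] = ready.astype(int)
    if n_missing:
        logger.info("treated %d missing item flags as not available", n_missing)
    return out


def stratum_readiness(facilities: pd.DataFrame, checklist: Checklist) -> pd.DataFrame:
    """Weighted per-stratum readiness proportions.

    For stratum ``s`` and intervention ``j``,
    ``r_sj = sum_i(w_i * ready_ij) / sum_i(w_i)`` over facilities ``i`` in
    ``s``. Strata with no contributing facility are absent from the result
    (never zero-filled). Records with a non-positive weight or a missing
    stratum classifier are rejected with a logged count: the stratum is the
    join key and cannot be imputed.

    Returns
    -------
    pandas.DataFrame
        Indexed by (facility_type, authority, location); one column per
        intervention plus ``facility_count`` (sum of weights) and
        ``n_facilities`` (unweighted count).
    """
    if len(facilities) == 0:
        raise ValueError("no facility records supplied")
    keep = pd.Series(True, index=facilities.index)
    bad_weight = ~(facilities["weight"] > 0)
    bad_stratum = facilities[STRATUM_COLS].isna().any(axis=1)
    if bad_weight.any():
        logger.warning("rejected %d facilities with non-positive weight", int(bad_weight.sum()))
    if bad_stratum.any():
        logger.warning(
            "rejected %d facilities with missing stratum classifiers", int(bad_stratum.sum())
        )
    keep &= ~bad_weight & ~bad_stratum
    facilities = facilities.loc[keep]
    if len(facilities) == 0:
        raise ValueError("all facility records were rejected")

    scores = score_facilities(facilities, checklist)
    w = facilities["weight"]
    grouped = scores.mul(w, axis=0).groupby([facilities[c] for c in STRATUM_COLS]).sum()
    wsum = w.groupby([facilities[c] for c in STRATUM_COLS]).sum()
    table = grouped.div(wsum, axis=0)
    table["facility_count"] = wsum
    table["n_facilities"] = facilities.groupby(STRATUM_COLS).size()
    table.index.names = STRATUM_COLS
    return table
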
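"""Stratum-level linking of care-seeking to facility readiness.

Availability coverage for an intervention is the sum over strata of the
care-seeking share times the readiness proportion:

    coverage = sum_s c_s * r_s

Linking happens at the stratum level (facility type x authority x location),
never at the individual level. Care-seeking strata with no readiness
counterpart are resolved by a collapse cascade — drop location, then
authority, never facility type, re-aggregating readiness by weighted
facility counts at each step — and anything still unmatched contributes
zero and is reported, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

from .careseeking import StratumCareseekingTable
from .strata import STRATUM_COLS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageEstimate:
    """A per-intervention availability-coverage point estimate."""

    intervention: str
    value: float
    method: str  # "linked", "proxy" or "predicted"
    n_strata_used: int
    unmatched_careseeking_share: float


def _collapse(readiness: pd.DataFrame, keep_cols: List[str]) -> pd.DataFrame:
    """Re-aggregate readiness over dropped stratum dimensions.

    Readiness proportions are recombined as means weighted by the (already
    weighted) facility counts, so collapsing is equivalent to recomputing the
    proportions on the pooled facilities.
    """
    counts = readiness["facility_count"]
    value_cols = [c for c in readiness.columns if c not in ("facility_count", "n_facilities")]
    weighted = readiness[value_cols].mul(counts, axis=0)
    grouped = weighted.groupby(level=keep_cols).sum()
    csum = counts.groupby(level=keep_cols).sum()
    out = grouped.div(csum, axis=0)
    out["facility_count"] = csum
    return out


def match_strata(
    careseeking_shares: pd.Series, readiness: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.Series]:
    """Match each care-seeking stratum to a readiness row.

    Returns
    -------
    matched : DataFrame
        One row per matched care-seeking stratum: the share ``c``, the
        readiness columns, and ``match_level`` (``exact``, ``no_location``
        or ``type_only``).
    unmatched : Series
        Care-seeking shares that found no readiness row at any cascade level.
    """
    if len(careseeking_shares) == 0:
        return (
            pd.DataFrame(columns=["c", "match_level"]),
            pd.Series(dtype=float),
        )
    collapsed_loc = _collapse(readiness, STRATUM_COLS[:2])  # by (type, authority)
    collapsed_auth = _collapse(readiness, STRATUM_COLS[:1])  # by type only

    rows = []
    unmatched_idx = []
    for stratum, share in careseeking_shares.items():
        ftype, auth, loc = stratum
        if stratum in readiness.index:
            src, level, key = readiness, "exact", stratum
        elif (ftype, auth) in collapsed_loc.index:
            src, level, key = collapsed_loc, "no_location", (ftype, auth)
        elif ftype in collapsed_auth.index:
            src, level, key = collapsed_auth, "type_only", ftype
        else:
            unmatched_idx.append(stratum)
            continue
        row = src.loc[key].to_dict()
        row.pop("facility_count", None)
        row.pop("n_facilities", None)
        row["c"] = share
        row["match_level"] = level
        rows.append((stratum, row))

    matched = pd.DataFrame(
        [r for _, r in rows],
        index=pd.MultiIndex.from_tuples([s for s, _ in rows], names=STRATUM_COLS)
        if rows
        else pd.MultiIndex.from_tuples([], names=STRATUM_COLS),
    )
    unmatched = careseeking_shares.loc[unmatched_idx] if unmatched_idx else pd.Series(dtype=float)
    if len(unmatched):
        logger.warning(
            "%d care-seeking strata (share %.4f) found no readiness match",
            len(unmatched), float(unmatched.sum()),
        )
    return matched, unmatched


def link_coverage(
    careseeking: StratumCareseekingTable,
    readiness: pd.DataFrame,
    intervention: str,
) -> CoverageEstimate:
    """Linked availability-coverage estimate for one intervention.

    ``value = sum_s c_s * r_s`` over matched strata; unmatched care-seeking
    shares (and the non-facility share) contribute zero. Raises if no
    stratum matches at all — a silent zero would be indistinguishable from
    genuine zero readiness.
    """
    if intervention not in readiness.columns:
        raise KeyError(f"intervention {intervention!r} not in the readiness table")
    matched, unmatched = match_strata(careseeking.shares, readiness)
    if len(careseeking.shares) > 0 and len(matched) == 0:
        raise ValueError(
            "no care-seeking stratum could be matched to the readiness table"
        )
    value = float((matched["c"] * matched[intervention]).sum()) if len(matched) else 0.0
    return CoverageEstimate(
        intervention=intervention,
        value=value,
        method="linked",
        n_strata_used=int(len(matched)),
        unmatched_careseeking_share=float(unmatched.sum()) if len(unmatched) else 0.0,
    )
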
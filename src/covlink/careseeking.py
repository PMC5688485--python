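"""Household-side estimation: eligibility, ANC4+ coverage, care-seeking strata.

All proportions are sampling-weighted point estimates (the design enters
through the weights only; no variance estimation here). The recall window is
half-open: a birth is eligible when it occurred strictly less than 36
completed months before the survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strata import COMPONENTS, NON_FACILITY, STRATUM_COLS

logger = logging.getLogger(__name__)

ELIGIBILITY_MONTHS = 36
EARLY_ANC_MONTH = 4  # first visit within the first 4 months of pregnancy, inclusive


@dataclass(frozen=True)
class CountryCovariates:
    """Country-level ANC covariate rates on the [0, 1] proportion scale."""

    anc4_rate: float
    blood_sample_rate: float
    urine_sample_rate: float
    bp_rate: float
    early_anc_rate: float

    def as_dict(self) -> dict:
        return {
            "anc4_rate": self.anc4_rate,
            "blood_sample_rate": self.blood_sample_rate,
            "urine_sample_rate": self.urine_sample_rate,
            "bp_rate": self.bp_rate,
            "early_anc_rate": self.early_anc_rate,
        }


@dataclass
class StratumCareseekingTable:
    """Distribution of ANC4+ coverage across facility strata.

    ``shares`` holds c_s, the weighted share of *all eligible women* who
    attended 4+ ANC visits with a care source in stratum s; the non-facility
    bucket (ANC4+ women without a facility source) is kept separate so the
    partition ``sum_s c_s + non_facility_share == anc4_coverage`` holds
    exactly.
    """

    shares: pd.Series  # indexed by (facility_type, authority, location)
    non_facility_share: float
    anc4_coverage: float


def _check_unique_women(records: pd.DataFrame) -> None:
    if "woman_id" in records.columns and records["woman_id"].duplicated().any():
        dup = records.loc[records["woman_id"].duplicated(), "woman_id"].iloc[0]
        raise ValueError(f"duplicate woman_id {dup!r}: expected one record per woman")


def filter_eligible(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to births within the 3-year recall window.

    Keeps records with ``0 <= months_since_birth < 36``; records with
    negative months are rejected (logged separately from the window
    exclusions). Idempotent.
    """
    _check_unique_women(records)
    months = records["months_since_birth"]
    negative = months < 0
    if negative.any():
        logger.warning("rejected %d records with negative months_since_birth",
                       int(negative.sum()))
    kept = records.loc[~negative & (months < ELIGIBILITY_MONTHS)].copy()
    n_excluded = len(records) - len(kept)
    logger.info("eligibility filter: kept %d of %d records (%d excluded)",
                len(kept), len(records), n_excluded)
    kept.attrs["n_excluded"] = n_excluded
    return kept


def _weighted_share(flags: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(weights * flags) / np.sum(weights))


def anc4_coverage(records: pd.DataFrame) -> float:
    """Weighted proportion of eligible women with 4+ ANC visits."""
    if len(records) == 0:
        raise ValueError("cannot estimate ANC4+ coverage from zero records")
    w = records["weight"].to_numpy(dtype=float)
    return _weighted_share((records["anc_visits"] >= 4).to_numpy(), w)


def stratum_careseeking(records: pd.DataFrame) -> StratumCareseekingTable:
    """Per-stratum care-seeking shares c_s among all eligible women.

    ANC4+ women with a null care source (home, traditional care, or simply
    unreported) are counted in ``non_facility_share`` — never silently
    dropped — and contribute zero availability coverage downstream, since
    facility readiness is undefined outside facilities.
    """
    if len(records) == 0:
        return StratumCareseekingTable(
            shares=pd.Series(dtype=float), non_facility_share=0.0, anc4_coverage=0.0
        )
    w = records["weight"].to_numpy(dtype=float)
    wsum = w.sum()
    anc4 = records["anc_visits"] >= 4
    overall = float(np.sum(w[anc4]) / wsum)

    facility = anc4 & records["source_type"].notna() & records["source_authority"].notna()
    sub = records.loc[facility]
    if len(sub):
        key = [sub["source_type"], sub["source_authority"], sub["residence"]]
        shares = sub["weight"].groupby(key).sum() / wsum
        shares.index.names = STRATUM_COLS
        shares.name = "c"
    else:
        shares = pd.Series(dtype=float, name="c")
        shares.index = pd.MultiIndex.from_tuples([], names=STRATUM_COLS)
    non_facility = overall - float(shares.sum())
    # clamp the tiny negative that pure float cancellation can produce
    non_facility = max(non_facility, 0.0)
    return StratumCareseekingTable(
        shares=shares, non_facility_share=non_facility, anc4_coverage=overall
    )


def covariate_rates(records: pd.DataFrame, denominator: str = "all") -> CountryCovariates:
    """Country-level ANC covariate rates used by the prediction models.

    Parameters
    ----------
    records
        Eligible woman records.
    denominator
        ``"all"`` (default): component and early-ANC rates are computed over
        all eligible women, with non-attenders contributing zero — matching
        their use as country-level predictors alongside ``anc4_rate``.
        ``"anc"``: rates among women with at least one ANC visit.
    """
    if len(records) == 0:
        raise ValueError("cannot compute covariate rates from zero records")
    if denominator not in ("all", "anc"):
        raise ValueError(f"denominator must be 'all' or 'anc', got {denominator!r}")
    if denominator == "anc":
        base = records.loc[records["anc_visits"] > 0]
        if len(base) == 0:
            raise ValueError("no ANC attenders among the eligible records")
    else:
        base = records
    w = base["weight"].to_numpy(dtype=float)
    early = (base["first_visit_month"] <= EARLY_ANC_MONTH).fillna(False).to_numpy()
    return CountryCovariates(
        anc4_rate=anc4_coverage(records),
        blood_sample_rate=_weighted_share(base["comp_blood_sample"].to_numpy(bool), w),
        urine_sample_rate=_weighted_share(base["comp_urine_sample"].to_numpy(bool), w),
        bp_rate=_weighted_share(base["comp_blood_pressure"].to_numpy(bool), w),
        early_anc_rate=_weighted_share(early, w),
    )
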
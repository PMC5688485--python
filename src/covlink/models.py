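"""Coverage prediction models and the LiST default proxy rules.

Three routes to a coverage number live here:

* ``stepwise_select`` — fit a fractional logit of linked coverage on
  country-level ANC covariates, choosing at most two slopes by stepwise
  selection with entry/exit at p = 0.1;
* ``PUBLISHED_COEFFICIENTS`` + ``predict_coverage`` — apply the published
  LiST ANC coverage prediction models through the logit link;
* ``default_proxy`` — the Lives Saved Tool's current default rules that
  impute intervention coverage from ANC4+ alone.

Covariates and predictions are proportions on [0, 1]; the proxy rules speak
percent, as the tool does, so the conversion is explicit at this boundary.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import special

from .careseeking import CountryCovariates
from .fraclogit import FractionalLogit, FractionalLogitResults
from .strata import COVARIATE_ORDER

__all__ = [
    "PUBLISHED_COEFFICIENTS",
    "stepwise_select",
    "predict_coverage",
    "default_proxy",
    "fit_fractional_logit",
]

#: Published coefficient sets of the LiST ANC coverage prediction models
#: (logit scale, covariates as proportions). Note: the hypertensive-disorders
#: model is transcribed with its slope on the urine-sample rate as published,
#: although blood-pressure measurement is the clinically expected predictor
#: for that intervention — the discrepancy is deliberate and documented, not
#: resolved silently.
PUBLISHED_COEFFICIENTS: Dict[str, Dict[str, float]] = {
    "syphilis": {"intercept": -1.22, "blood_sample_rate": 3.36, "early_anc_rate": -5.23},
    "diabetes": {"intercept": -3.21, "blood_sample_rate": 2.61},
    "hypertensive_disorders": {"intercept": -1.62, "urine_sample_rate": 2.50},
    "malaria": {"intercept": -1.64, "blood_sample_rate": 2.92},
    "pre_eclampsia": {
        "intercept": -6.44,
        "blood_sample_rate": 4.91,
        "anc4_rate": 2.56,
    },
}

#: Tiered multiplier applied to ANC4+ (percent) by the syphilis default proxy:
#: <40 -> 0.20, [40, 75) -> 0.50, [75, 95) -> 0.70, >=95 -> 1.00.
SYPHILIS_TIERS = ((40.0, 0.20), (75.0, 0.50), (95.0, 0.70), (float("inf"), 1.00))

#: Flat share of ANC4+ assumed screened and managed for the four
#: case-management interventions.
CASE_MANAGEMENT_FACTOR = 0.05


def fit_fractional_logit(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    weights: Optional[str] = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FractionalLogitResults:
    """Convenience wrapper: build and fit a fractional logit from columns."""
    model = FractionalLogit.from_dataframe(data, response, covariates, weights=weights)
    return model.fit(max_iter=max_iter, tol=tol)


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str] = tuple(COVARIATE_ORDER),
    p_enter: float = 0.1,
    p_exit: float = 0.1,
    max_terms: int = 2,
) -> FractionalLogitResults:
    """Forward stepwise selection with backward pruning, capped at two slopes.

    At each forward step the candidate with the smallest p-value below
    ``p_enter`` enters (ties broken by the fixed candidate order); after each
    entry, any included term whose p-value has risen to ``p_exit`` or above
    is removed (worst first). Iterates to a fixed point and never exceeds
    ``max_terms`` slopes. If no candidate ever enters, the intercept-only
    model is returned. Deterministic given the data.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    selected: list = []
    visited = set()
    while True:
        state = tuple(selected)
        if state in visited:  # selection cycle: stop at the repeated state
            break
        visited.add(state)
        changed = False
        # forward step
        if len(selected) < max_terms:
            best_term, best_p = None, p_enter
            for cand in candidates:
                if cand in selected:
                    continue
                res = fit_fractional_logit(data, response, selected + [cand])
                if not res.converged:
                    continue
                p = res.pvalues[res.exog_names.index(cand)]
                if p < best_p:
                    best_term, best_p = cand, p
            if best_term is not None:
                selected.append(best_term)
                changed = True
        # backward pruning
        while selected:
            res = fit_fractional_logit(data, response, selected)
            slope_ps = {t: res.pvalues[res.exog_names.index(t)] for t in selected}
            worst = max(slope_ps, key=lambda t: slope_ps[t])
            if slope_ps[worst] >= p_exit:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return fit_fractional_logit(data, response, selected)


def predict_coverage(
    model: Union[FractionalLogitResults, Mapping[str, float]],
    covariates: Union[CountryCovariates, Mapping[str, float]],
) -> float:
    """Predicted coverage logit^{-1}(b0 + sum_j b_j x_j), strictly in (0, 1).

    ``model`` is either fitted results or a published coefficient mapping
    with an ``"intercept"`` key. A covariate required by the model but
    absent from ``covariates`` raises a ``KeyError`` naming the term.
    """
    if isinstance(model, FractionalLogitResults):
        return model.predict_from_covariates(covariates)
    eta = float(model["intercept"])
    for term, beta in model.items():
        if term == "intercept":
            continue
        if isinstance(covariates, Mapping):
            if term not in covariates:
                raise KeyError(f"missing covariate {term!r}")
            x = float(covariates[term])
        else:
            if not hasattr(covariates, term):
                raise KeyError(f"missing covariate {term!r}")
            x = float(getattr(covariates, term))
        eta += beta * x
    return float(special.expit(eta))


def default_proxy(intervention: str, anc4_percent: float) -> float:
    """Current LiST default proxy coverage, returned as a proportion.

    ``anc4_percent`` is ANC4+ coverage in percent (0-100). For syphilis
    detection and treatment the proxy is a tiered multiple of ANC4+
    (20%/50%/70%/100% of ANC4+ as ANC4+ crosses 40, 75 and 95); for the four
    case-management interventions it is a flat 5% of ANC4+. The proxy can
    therefore never exceed ANC4+ itself.
    """
    anc4_percent = float(anc4_percent)
    if not 0.0 <= anc4_percent <= 100.0:
        raise ValueError(f"anc4_percent must lie in [0, 100], got {anc4_percent}")
    if intervention == "syphilis":
        for upper, mult in SYPHILIS_TIERS:
            if anc4_percent < upper:
                return mult * anc4_percent / 100.0
        raise AssertionError("unreachable: tiers cover [0, 100]")
    if intervention in PUBLISHED_COEFFICIENTS:
        return CASE_MANAGEMENT_FACTOR * anc4_percent / 100.0
    raise KeyError(f"unknown intervention {intervention!r}")
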
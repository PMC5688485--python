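"""Synthetic household-survey and facility-assessment microdata.

Real inputs to the linking approach (DHS-style household surveys, SPA/SARA
facility assessments) are not redistributable, so this module generates
survey microdata with a *known* ground-truth availability coverage, plus
multi-country panels with a known fractional-logit data-generating process.
Every downstream stage of the pipeline can therefore be tested against a
closed-form truth.

The household generator emulates: two-stage cluster sampling with positive
weights, a months-since-birth recall window, an ANC visit-count law with a
directly configurable P(visits >= 4), Bernoulli receipt of ANC components,
and — for ANC4+ women only — a categorical care source over facility strata
(plus a non-facility share). The facility generator emulates a facility
roster with per-stratum Bernoulli item availability arranged so that each
facility's conjunctive readiness score for intervention j is an exact
Bernoulli draw with the configured stratum rate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .readiness import Checklist, default_checklist
from .strata import (
    COMPONENTS,
    COVARIATE_ORDER,
    INTERVENTIONS,
    NON_FACILITY,
    STRATUM_COLS,
    Stratum,
)

__all__ = [
    "SimConfig",
    "PanelConfig",
    "default_sim_config",
    "default_panel_config",
    "generate_household_survey",
    "generate_facility_survey",
    "generate_country_panel",
    "true_availability_coverage",
]


class ConfigurationError(ValueError):
    """A simulation config field violates its invariants."""


# --- default study conditions -------------------------------------------------

_DEFAULT_STRATA: List[Stratum] = [
    ("hospital", "public", "urban"),
    ("hospital", "public", "rural"),
    ("hospital", "non_public", "urban"),
    ("health_center", "public", "urban"),
    ("health_center", "public", "rural"),
    ("health_center", "non_public", "rural"),
    ("health_post", "public", "rural"),
    ("health_post", "public", "urban"),
]

# Where ANC4+ women sought care: hospitals and public health centers dominate,
# with a small non-facility share (home/traditional care).
_DEFAULT_CARESEEKING: Dict[object, float] = {
    ("hospital", "public", "urban"): 0.18,
    ("hospital", "public", "rural"): 0.10,
    ("hospital", "non_public", "urban"): 0.07,
    ("health_center", "public", "urban"): 0.12,
    ("health_center", "public", "rural"): 0.25,
    ("health_center", "non_public", "rural"): 0.06,
    ("health_post", "public", "rural"): 0.12,
    ("health_post", "public", "urban"): 0.04,
    NON_FACILITY: 0.06,
}

# Facility roster composition (share of sampled facilities per stratum).
_DEFAULT_FACILITY_SHARES: Dict[Stratum, float] = {
    ("hospital", "public", "urban"): 0.06,
    ("hospital", "public", "rural"): 0.05,
    ("hospital", "non_public", "urban"): 0.04,
    ("health_center", "public", "urban"): 0.15,
    ("health_center", "public", "rural"): 0.25,
    ("health_center", "non_public", "rural"): 0.10,
    ("health_post", "public", "rural"): 0.25,
    ("health_post", "public", "urban"): 0.10,
}

# Baseline readiness by facility type; per-intervention multipliers reflect
# that simple equipment (BP apparatus) is more common than lab tests + drugs.
_TYPE_BASE = {"hospital": 0.85, "health_center": 0.55, "health_post": 0.30}
_INTERVENTION_MULT = {
    "syphilis": 0.75,
    "diabetes": 0.85,
    "hypertensive_disorders": 1.10,
    "malaria": 1.00,
    "pre_eclampsia": 0.65,
}


def _default_readiness_rates(strata: Sequence[Stratum]) -> Dict[Stratum, Dict[str, float]]:
    rates: Dict[Stratum, Dict[str, float]] = {}
    for s in strata:
        ftype, authority, location = s
        base = _TYPE_BASE[ftype]
        if authority == "non_public":
            base *= 1.05
        if location == "urban":
            base *= 1.05
        rates[s] = {
            iv: float(min(0.98, base * _INTERVENTION_MULT[iv])) for iv in INTERVENTIONS
        }
    return rates


@dataclass
class SimConfig:
    """One simulated country: sampling design and true rates.

    The defaults are the package's reference study conditions: a mid-sized
    two-stage household sample, a facility roster dominated by health
    centers and posts, ANC4+ coverage of 0.55, and readiness rates graded by
    facility type.
    """

    n_clusters: int = 100
    women_per_cluster: int = 20
    n_facilities: int = 400
    strata: List[Stratum] = field(default_factory=lambda: list(_DEFAULT_STRATA))
    careseeking_shares: Dict[object, float] = field(
        default_factory=lambda: dict(_DEFAULT_CARESEEKING)
    )
    facility_shares: Optional[Dict[Stratum, float]] = None
    p_anc4: float = 0.55
    p_early: float = 0.45
    component_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "blood_pressure": 0.85,
            "urine_sample": 0.60,
            "blood_sample": 0.60,
            "weight": 0.85,
            "height": 0.50,
        }
    )
    readiness_rates: Optional[Dict[Stratum, Dict[str, float]]] = None
    visit_count_law: Dict[str, float] = field(
        default_factory=lambda: {"zero_inflation": 0.12, "lam": 2.2, "lam_extra": 1.2}
    )
    weight_law: Dict[str, object] = field(
        default_factory=lambda: {"kind": "lognormal", "sigma": 0.35}
    )
    months_range: int = 60  # months-since-birth ~ Uniform{0, ..., months_range-1}
    p_urban: float = 0.38  # residence of women without a facility care source
    item_background_rate: float = 0.85  # availability of non-signature items
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_clusters <= 0 or self.women_per_cluster <= 0:
            raise ConfigurationError("n_clusters and women_per_cluster must be positive")
        if self.readiness_rates is None:
            self.readiness_rates = _default_readiness_rates(self.strata)
        if self.facility_shares is None:
            total = sum(_DEFAULT_FACILITY_SHARES.get(s, 0.0) for s in self.strata)
            if total > 0:
                self.facility_shares = {
                    s: _DEFAULT_FACILITY_SHARES.get(s, 0.0) / total for s in self.strata
                }
            else:
                self.facility_shares = {s: 1.0 / len(self.strata) for s in self.strata}
        shares = np.array(list(self.careseeking_shares.values()), dtype=float)
        if abs(shares.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"careseeking_shares must sum to 1, got {shares.sum()!r}"
            )
        if (shares < 0).any() or (shares > 1).any():
            raise ConfigurationError("careseeking_shares entries must lie in [0, 1]")
        for name, p in [
            ("p_anc4", self.p_anc4),
            ("p_early", self.p_early),
            ("p_urban", self.p_urban),
            ("item_background_rate", self.item_background_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for comp, p in self.component_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"component_probs[{comp!r}] out of [0, 1]")
        stratum_set = set(self.strata)
        for key in self.careseeking_shares:
            if key != NON_FACILITY and key not in stratum_set:
                raise ConfigurationError(
                    f"careseeking_shares stratum {key!r} not listed in strata"
                )
        for s, per_iv in self.readiness_rates.items():
            if s not in stratum_set:
                raise ConfigurationError(f"readiness_rates stratum {s!r} not in strata")
            for iv, p in per_iv.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"readiness_rates[{s!r}][{iv!r}] out of [0, 1]"
                    )
        if self.n_facilities < len(self.strata):
            raise ConfigurationError(
                "n_facilities must be at least the number of strata so every "
                "stratum receives a facility"
            )

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class PanelConfig:
    """Multi-country panel with a known fractional-logit coverage process.

    Observed coverage for intervention j in country c is
    ``logit^{-1}(x_c . beta_j + eps)`` with ``eps ~ N(0, noise_sd^2)``,
    clipped to the open unit interval. Country covariate rates are drawn
    uniformly on realistic per-covariate ranges.
    """

    n_countries: int = 20
    true_beta: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "pre_eclampsia": {
                "intercept": -6.44,
                "blood_sample_rate": 4.91,
                "anc4_rate": 2.56,
            }
        }
    )
    covariate_law: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "blood_sample_rate": (0.30, 0.95),
            "urine_sample_rate": (0.30, 0.95),
            "bp_rate": (0.40, 0.98),
            "early_anc_rate": (0.20, 0.80),
            "anc4_rate": (0.30, 0.95),
        }
    )
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ConfigurationError("n_countries must be at least 3")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for cov, (lo, hi) in self.covariate_law.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"covariate_law[{cov!r}] must satisfy 0<=lo<=hi<=1")
        for iv, coefs in self.true_beta.items():
            if "intercept" not in coefs:
                raise ConfigurationError(f"true_beta[{iv!r}] lacks an intercept")
            for term in coefs:
                if term != "intercept" and term not in self.covariate_law:
                    raise ConfigurationError(
                        f"true_beta[{iv!r}] term {term!r} has no covariate_law entry"
                    )


def default_sim_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def default_panel_config(**overrides) -> PanelConfig:
    return PanelConfig(**overrides)


# --- random streams -----------------------------------------------------------


def _streams(seed: int) -> Dict[str, np.random.Generator]:
    """Independent per-purpose generators derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "household": np.random.default_rng(children[0]),
        "facility": np.random.default_rng(children[1]),
        "panel": np.random.default_rng(children[2]),
    }


def _draw_weights(law: Mapping[str, object], n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law.get("kind", "lognormal")
    if kind == "constant":
        return np.ones(n)
    if kind == "lognormal":
        sigma = float(law.get("sigma", 0.35))
        w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
        return w / np.exp(sigma**2 / 2.0)  # mean-one weights
    raise ConfigurationError(f"unknown weight_law kind {kind!r}")


# --- household survey ---------------------------------------------------------


def _visit_counts(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """ANC visit counts with P(visits >= 4) = p_anc4 exactly.

    ANC4+ women get 4 + Poisson(lam_extra) visits; the rest follow a
    zero-inflated Poisson truncated to {0, 1, 2, 3}, so the ANC4+ margin —
    the only margin the analysis uses — is matched by construction.
    """
    law = config.visit_count_law
    anc4 = rng.random(n) < config.p_anc4
    visits = np.zeros(n, dtype=int)
    visits[anc4] = 4 + rng.poisson(float(law["lam_extra"]), size=int(anc4.sum()))

    n_low = int((~anc4).sum())
    lam = float(law["lam"])
    pmf = np.array([lam**k / math.factorial(k) for k in range(4)]) * np.exp(-lam)
    pmf[0] += 1e-300  # guard fully degenerate laws
    probs = pmf / pmf.sum()
    low = rng.choice(4, size=n_low, p=probs)
    zero = rng.random(n_low) < float(law["zero_inflation"])
    low[zero] = 0
    visits[~anc4] = low
    return visits


def generate_household_survey(config: SimConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one country's household survey (one row per woman).

    Columns: woman_id, cluster_id, months_since_birth, anc_visits,
    first_visit_month (NaN when no ANC), comp_* receipt flags, source_type /
    source_authority (None unless the woman is ANC4+ with a facility
    source), residence, weight.
    """
    config.validate()
    rng = _streams(config.seed if seed is None else seed)["household"]
    n = config.n_clusters * config.women_per_cluster

    cluster_id = np.repeat([f"c{ix:04d}" for ix in range(config.n_clusters)],
                           config.women_per_cluster)
    months = rng.integers(0, config.months_range, size=n)
    visits = _visit_counts(config, n, rng)
    any_anc = visits > 0

    first_month = np.full(n, np.nan)
    early = rng.random(n) < config.p_early
    first_month[any_anc & early] = rng.integers(1, 5, size=int((any_anc & early).sum()))
    first_month[any_anc & ~early] = rng.integers(5, 10, size=int((any_anc & ~early).sum()))

    comps = {}
    for comp in COMPONENTS:
        received = np.zeros(n, dtype=bool)
        received[any_anc] = rng.random(int(any_anc.sum())) < config.component_probs[comp]
        comps[f"comp_{comp}"] = received

    # care source: ANC4+ women only
    keys = list(config.careseeking_shares.keys())
    probs = np.array([config.careseeking_shares[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    anc4 = visits >= 4
    source_type = np.full(n, None, dtype=object)
    source_auth = np.full(n, None, dtype=object)
    residence = np.where(rng.random(n) < config.p_urban, "urban", "rural").astype(object)
    if anc4.any():
        drawn = rng.choice(len(keys), size=int(anc4.sum()), p=probs)
        idx = np.flatnonzero(anc4)
        for j, key_ix in zip(idx, drawn):
            key = keys[key_ix]
            if key == NON_FACILITY:
                continue
            ftype, auth, loc = key
            source_type[j] = ftype
            source_auth[j] = auth
            residence[j] = loc

    df = pd.DataFrame(
        {
            "woman_id": [f"w{ix:06d}" for ix in range(n)],
            "cluster_id": cluster_id,
            "months_since_birth": months,
            "anc_visits": visits,
            "first_visit_month": first_month,
            **comps,
            "source_type": source_type,
            "source_authority": source_auth,
            "residence": residence,
            "weight": _draw_weights(config.weight_law, n, rng),
        }
    )
    return df


# --- facility survey ----------------------------------------------------------


def _signature_items(checklist: Checklist) -> Dict[str, str]:
    """One checklist item unique to each intervention (drives its readiness)."""
    counts: Dict[str, int] = {}
    for items in checklist.values():
        for item in items:
            counts[item] = counts.get(item, 0) + 1
    signatures = {}
    for intervention, items in checklist.items():
        unique = [i for i in items if counts[i] == 1]
        if not unique:
            raise ConfigurationError(
                f"no item unique to intervention {intervention!r}; the generator "
                "needs one signature item per intervention"
            )
        signatures[intervention] = unique[-1]
    return signatures


def generate_facility_survey(
    config: SimConfig,
    checklist: Optional[Checklist] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Generate one country's facility assessment (one row per facility).

    Item flags are arranged so that the conjunctive readiness score of
    facility i for intervention j is exactly a Bernoulli draw with the
    configured ``readiness_rates`` of its stratum: the intervention's
    signature item equals the readiness draw, every other required item is
    forced available whenever any intervention needing it is ready and is
    otherwise available with ``item_background_rate``. Every configured
    stratum receives at least one facility (the first ``len(strata)``
    facilities are allocated deterministically, one per stratum).
    """
    config.validate()
    if checklist is None:
        checklist = default_checklist()
    rng = _streams(config.seed if seed is None else seed)["facility"]
    signatures = _signature_items(checklist)
    n = config.n_facilities
    strata = list(config.strata)

    shares = np.array([config.facility_shares[s] for s in strata], dtype=float)
    shares = shares / shares.sum()
    assignment = np.concatenate(
        [np.arange(len(strata)), rng.choice(len(strata), size=n - len(strata), p=shares)]
    )
    rng.shuffle(assignment)

    ftype = np.array([strata[k][0] for k in assignment], dtype=object)
    auth = np.array([strata[k][1] for k in assignment], dtype=object)
    loc = np.array([strata[k][2] for k in assignment], dtype=object)

    ready = {}
    for iv in checklist:
        rates = np.array(
            [config.readiness_rates[strata[k]].get(iv, 0.0) for k in assignment]
        )
        ready[iv] = rng.random(n) < rates

    all_items = sorted({i for items in checklist.values() for i in items})
    item_cols: Dict[str, np.ndarray] = {}
    for item in all_items:
        forced = np.zeros(n, dtype=bool)
        for iv, items in checklist.items():
            if item in items:
                forced |= ready[iv]
        background = rng.random(n) < config.item_background_rate
        item_cols[item] = forced | background
    for iv, sig in signatures.items():
        item_cols[sig] = ready[iv].copy()

    df = pd.DataFrame(
        {
            "facility_id": [f"f{ix:05d}" for ix in range(n)],
            "facility_type": ftype,
            "authority": auth,
            "location": loc,
            **item_cols,
            "weight": _draw_weights(config.weight_law, n, rng),
        }
    )
    return df


# --- closed-form truth --------------------------------------------------------


def true_availability_coverage(config: SimConfig, intervention: str) -> float:
    """Ground-truth availability coverage under the generator.

    Equals ``p_anc4 * sum_s careseeking_shares[s] * readiness_rates[s, j]``
    over facility strata (the non-facility share contributes zero), i.e. the
    expectation of the linked estimate. Lies in [0, p_anc4].
    """
    config.validate()
    assert config.readiness_rates is not None
    total = 0.0
    for key, share in config.careseeking_shares.items():
        if key == NON_FACILITY:
            continue
        per_iv = config.readiness_rates[key]
        if intervention not in per_iv:
            raise KeyError(f"unknown intervention {intervention!r} in readiness_rates")
        total += share * per_iv[intervention]
    return config.p_anc4 * total


# --- multi-country panel ------------------------------------------------------


def generate_country_panel(config: PanelConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Country-level panel of covariate rates and observed coverages.

    One row per country with the five covariate rates plus one
    ``coverage_<intervention>`` column per entry of ``true_beta``.
    """
    rng = _streams(config.seed if seed is None else seed)["panel"]
    n = config.n_countries
    data: Dict[str, np.ndarray] = {"country": np.array([f"country_{ix:03d}" for ix in range(n)])}
    for cov in COVARIATE_ORDER:
        lo, hi = config.covariate_law.get(cov, (0.0, 1.0))
        data[cov] = rng.uniform(lo, hi, size=n)
    eps_tiny = 1e-9
    for iv, coefs in config.true_beta.items():
        eta = np.full(n, coefs["intercept"], dtype=float)
        for term, beta in coefs.items():
            if term == "intercept":
                continue
            eta = eta + beta * data[term]
        if config.noise_sd > 0:
            eta = eta + rng.normal(0.0, config.noise_sd, size=n)
        coverage = 1.0 / (1.0 + np.exp(-eta))
        data[f"coverage_{iv}"] = np.clip(coverage, eps_tiny, 1.0 - eps_tiny)
    return pd.DataFrame(data)
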
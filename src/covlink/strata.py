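"""Shared vocabulary for linking strata, interventions and table columns.

A *stratum* is the join key between the household-survey side (where women
sought antenatal care) and the facility-assessment side (which facilities
are ready to deliver an intervention): the cross-classification of facility
type, managing authority and urban/rural location.
"""

from __future__ import annotations

from typing import Tuple

Stratum = Tuple[str, str, str]

#: Column names of the stratum key, in cascade order (location is dropped
#: first when collapsing, then authority; facility type is never dropped).
STRATUM_COLS = ["facility_type", "authority", "location"]

#: Antenatal-care interventions whose availability coverage is estimated.
INTERVENTIONS = [
    "syphilis",
    "diabetes",
    "hypertensive_disorders",
    "malaria",
    "pre_eclampsia",
]

#: ANC components recorded per woman (received during any ANC visit).
COMPONENTS = ["blood_pressure", "urine_sample", "blood_sample", "weight", "height"]

#: Country-level covariates used by the coverage prediction models, in the
#: fixed order used for deterministic tie-breaking during stepwise selection.
COVARIATE_ORDER = [
    "blood_sample_rate",
    "urine_sample_rate",
    "bp_rate",
    "early_anc_rate",
    "anc4_rate",
]

#: Sentinel label for ANC sought outside the formal facility system (at home,
#: from a traditional attendant, ...). Such care has no readiness counterpart
#: and contributes zero to availability coverage.
NON_FACILITY = "non_facility"

HOUSEHOLD_COLUMNS = [
    "woman_id",
    "cluster_id",
    "months_since_birth",
    "anc_visits",
    "first_visit_month",
    *[f"comp_{c}" for c in COMPONENTS],
    "source_type",
    "source_authority",
    "residence",
    "weight",
]
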
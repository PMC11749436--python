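import datetime as dt

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from psnet.registry_io import VISIT_COLUMNS, VisitTable

_ROW_DEFAULTS = {
    "professional_id": "",
    "municipality": "A",
    "occupation_title": "",
    "occupation_group": "",
    "service_type": "",
    "service_group": "outpatient",
    "icd10_codes": "",
    "icpc2_codes": "",
    "home_care": False,
    "patient_age_years": 40,
}


def build_visit_table(rows):
    """Typed VisitTable from partial row dicts (defaults filled in)."""
    full = []
    for i, r in enumerate(rows):
        row = {**_ROW_DEFAULTS, **r}
        row.setdefault("visit_id", f"v{i:03d}")
        full.append(row)
    df = pd.DataFrame(full, columns=list(VISIT_COLUMNS))
    df["date"] = pd.to_datetime(df["date"])
    df["home_care"] = df["home_care"].astype(bool)
    df["patient_age_years"] = df["patient_age_years"].astype(int)
    return VisitTable(df)


@pytest.fixture
def make_table():
    return build_visit_table


def _prof(pid, muni, occ, svc):
    return {
        "professional_id": pid,
        "municipality": muni,
        "occupation_group": occ,
        "service_group": svc,
    }


# Professional shorthands for the toy register: X1/X3 physicians in
# outpatient care (municipalities A and B), X2 a mental-health nurse in A.
_X1 = _prof("X1", "A", "physician", "outpatient")
_X2 = _prof("X2", "A", "nurse", "mental_health_substance_use")
_X3 = _prof("X3", "B", "physician", "outpatient")


@pytest.fixture
def toy_register():
    """Six-patient register exercising every cohort-filter stage.

    Hand enumeration: p1 (4 visits, one with a missing professional) and
    p6 (one out-of-window visit, one home-care visit) survive; p2 is a
    single-visit patient, p3 sees a single professional, p4 has no MH/SU
    visit, p5 is a minor.
    """
    rows = [
        # p1, age 40: survives with visits v01, v02, v03
        {"visit_id": "v01", "patient_id": "p1", "date": "2021-01-05", **_X1,
         "icd10_codes": "F32.1"},
        {"visit_id": "v02", "patient_id": "p1", "date": "2021-02-01", **_X2},
        {"visit_id": "v03", "patient_id": "p1", "date": "2021-03-01", **_X1},
        {"visit_id": "v04", "patient_id": "p1", "date": "2021-04-01"},  # no prof
        # p2: qualifying but single visit
        {"visit_id": "v05", "patient_id": "p2", "date": "2021-05-01", **_X1,
         "icd10_codes": "F41", "patient_age_years": 30},
        # p3: three visits, all to X2
        {"visit_id": "v06", "patient_id": "p3", "date": "2021-01-10", **_X2,
         "patient_age_years": 50},
        {"visit_id": "v07", "patient_id": "p3", "date": "2021-02-10", **_X2,
         "patient_age_years": 50},
        {"visit_id": "v08", "patient_id": "p3", "date": "2021-03-10", **_X2,
         "patient_age_years": 50},
        # p4: no MH/SU visit at all
        {"visit_id": "v09", "patient_id": "p4", "date": "2021-06-01", **_X1,
         "icd10_codes": "J06", "patient_age_years": 45},
        {"visit_id": "v10", "patient_id": "p4", "date": "2021-06-15", **_X3,
         "patient_age_years": 45},
        # p5: minor
        {"visit_id": "v11", "patient_id": "p5", "date": "2021-07-01", **_X1,
         "icd10_codes": "F32", "patient_age_years": 15},
        {"visit_id": "v12", "patient_id": "p5", "date": "2021-07-15", **_X2,
         "patient_age_years": 15},
        # p6, age 60: survives with v14, v16
        {"visit_id": "v13", "patient_id": "p6", "date": "2020-12-15", **_X1,
         "patient_age_years": 60},
        {"visit_id": "v14", "patient_id": "p6", "date": "2021-02-20", **_X1,
         "icd10_codes": "F33", "patient_age_years": 60},
        {"visit_id": "v15", "patient_id": "p6", "date": "2021-03-05", **_X3,
         "home_care": True, "patient_age_years": 60},
        {"visit_id": "v16", "patient_id": "p6", "date": "2021-03-20", **_X3,
         "patient_age_years": 60},
    ]
    return build_visit_table(rows)


def random_attributed_graph(seed, n=20, p=0.3, attributes=None):
    """G(n, p) with categorical node attributes drawn uniformly."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    attributes = attributes or {
        "municipality": ["A", "B", "C"],
        "occupation_group": ["physician", "nurse", "other"],
        "service_group": ["outpatient", "mental_health_substance_use", "other"],
    }
    for node in g.nodes:
        for attr, levels in attributes.items():
            g.nodes[node][attr] = levels[rng.integers(len(levels))]
    return g


@pytest.fixture
def attributed_graph_factory():
    return random_attributed_graph
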
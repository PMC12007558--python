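import numpy as np
import pandas as pd
import pytest

from harmony_bench import (
    CategoryMap,
    StudyData,
    preset_travelling_heads,
    simulate_study,
)


@pytest.fixture(scope="session")
def preset_run():
    """The seeded reference simulation shared across the suite."""
    spec, cfg = preset_travelling_heads(seed=1)
    study, truth = simulate_study(spec, cfg)
    return spec, cfg, study, truth


@pytest.fixture(scope="session")
def preset_study(preset_run):
    return preset_run[2]


@pytest.fixture(scope="session")
def preset_truth(preset_run):
    return preset_run[3]


def make_study(sessions_rows, idp_values, categories=None, iqm_values=None):
    """Hand-build a StudyData from compact row tuples.

    ``sessions_rows``: (session_id, subject_id, scanner_id, repeat_index)
    or full 8-tuples; ``idp_values``: mapping session_id -> list of values.
    """
    rows = []
    for r in sessions_rows:
        if len(r) == 4:
            sid, sub, scan, rep = r
            rows.append((sid, sub, scan, f"site-{scan}", f"vendor-{scan}", rep, 30.0, "M"))
        else:
            rows.append(r)
    sessions = pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "subject_id",
            "scanner_id",
            "site",
            "vendor",
            "repeat_index",
            "age",
            "sex",
        ],
    )
    n_idp = len(next(iter(idp_values.values())))
    idp_names = [f"idp_{i}" for i in range(n_idp)]
    idps = pd.DataFrame.from_dict(idp_values, orient="index", columns=idp_names)
    idps = idps.reindex(sessions["session_id"]).astype(float)
    if categories is None:
        cats = pd.DataFrame(
            {"category": "cat_a", "group": "grp_a", "modality": "synthetic"},
            index=pd.Index(idp_names, name="idp_name"),
        )
    else:
        cats = categories
    iqms = None
    if iqm_values is not None:
        n_iqm = len(next(iter(iqm_values.values())))
        iqms = pd.DataFrame.from_dict(
            iqm_values, orient="index", columns=[f"iqm_{i}" for i in range(n_iqm)]
        ).reindex(sessions["session_id"]).astype(float)
    study = StudyData(
        sessions=sessions, idps=idps, categories=CategoryMap(entries=cats), iqms=iqms
    )
    study.validate()
    return study


@pytest.fixture
def toy_study():
    """2 subjects x 2 scanners, subject A with one extra repeat on scanner 1."""
    rows = [
        ("A_s1_rep0", "A", "s1", 0),
        ("A_s1_rep1", "A", "s1", 1),
        ("A_s2_rep0", "A", "s2", 0),
        ("B_s1_rep0", "B", "s1", 0),
        ("B_s2_rep0", "B", "s2", 0),
    ]
    values = {
        "A_s1_rep0": [9.0, 1.0],
        "A_s1_rep1": [11.0, 3.0],
        "A_s2_rep0": [10.0, 2.0],
        "B_s1_rep0": [20.0, 4.0],
        "B_s2_rep0": [22.0, 6.0],
    }
    return make_study(rows, values)
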
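"""Shared fixtures: the study instrument, parameters and small datasets."""

import numpy as np
import pandas as pd
import pytest

import hemodce as h


@pytest.fixture(scope="session")
def aset():
    return h.hemophilia_attributes()


@pytest.fixture(scope="session")
def params():
    return h.study_parameters()


@pytest.fixture(scope="session")
def study_design():
    """One fixed study instrument: 18 D-efficient tasks, 2 blocks, status quo
    and one repeated task per block."""
    return h.build_study_design(seed=0, n_restarts=2)


@pytest.fixture(scope="session")
def small_dataset(study_design, params):
    """A fixed mid-size simulated survey at the study's parameters."""
    return h.simulate_study(n_respondents=120, params=params,
                            design=study_design, seed=11)


def make_manual_dataset(aset, rows):
    """Build a ChoiceDataset from (resp, task, alt, levels-dict, chosen) tuples."""
    records = []
    for resp, task, alt, levels, chosen in rows:
        rec = {
            "respondent_id": resp, "task_id": task, "block_id": 1, "alt_id": alt,
            "is_status_quo": 0, "is_repeat_of": np.nan, "is_practice": 0,
            "chosen": chosen,
        }
        for name in aset.names:
            rec[name] = levels.get(name)
        records.append(rec)
    return h.ChoiceDataset(pd.DataFrame.from_records(records), aset)


@pytest.fixture(scope="session")
def binary_attribute_set():
    """One categorical 2-level attribute: a single model column."""
    return h.AttributeSet((
        h.Attribute(name="speed", coding="categorical", levels=("slow", "fast"),
                    reference="slow", direction_hint="higher_better"),
    ))
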
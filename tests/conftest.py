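import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from judoba import load_cohort_config, table2_cohort_path
from judoba.accelio import summaries_frame, summarize_trace
from judoba.synthgen import generate_cohort
from judoba.types import ContestDesign, GroupSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def table2_specs():
    return load_cohort_config(table2_cohort_path())


@pytest.fixture(scope="session")
def default_design():
    return ContestDesign()


def make_spec(**overrides) -> GroupSpec:
    base = dict(
        sex="male",
        weight_class="light",
        n_athletes=4,
        vm_mean=9075.5,
        vm_sd=915.4,
        axis_share_means=(29.3, 31.1, 39.6),
        axis_share_sds=(4.3, 3.5, 2.2),
        hr_mean=170.0,
        hr_sd=9.0,
        bla_mean=11.8,
        bla_sd=3.1,
        rpe_mean=15.9,
        rpe_sd=2.1,
        age_mean=22.0,
        age_sd=3.0,
    )
    base.update(overrides)
    return GroupSpec(**base)


@pytest.fixture(scope="session")
def small_cohort(table2_specs):
    """Full six-cell cohort at the study size (16/cell), seed 7."""
    return generate_cohort(table2_specs, ContestDesign(), seed=7)


@pytest.fixture(scope="session")
def small_cohort_frames(small_cohort):
    """(summaries DataFrame with physiology, manifest DataFrame)."""
    summaries = []
    manifest_rows = []
    for profile, trace, physio in small_cohort:
        summaries.append(summarize_trace(trace, physio))
        manifest_rows.append(
            {
                "athlete_id": profile.athlete_id,
                "sex": profile.sex,
                "weight_class": profile.weight_class,
            }
        )
    return summaries_frame(summaries), pd.DataFrame(manifest_rows)
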
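import pytest
from hypothesis import HealthCheck, settings

from sctbias.trial_io import CohortTable, RawSummary, TrialRecord

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(
    trial_id="T1",
    mean_a=65.2,
    sd_a=10.1,
    n_a=50,
    mean_b=64.8,
    sd_b=9.7,
    n_b=52,
    overall="low",
    domain1="low",
    variable="age",
    kind="mean_sd",
):
    """Two-arm mean(SD) trial record with adjustable fields."""
    return TrialRecord(
        trial_id=trial_id,
        variable_name=variable,
        arm_a=RawSummary(kind, mean_a, sd_a, None, n_a),
        arm_b=RawSummary(kind, mean_b, sd_b, None, n_b),
        rob2_overall=overall,
        rob2_domain1=domain1,
    )


@pytest.fixture
def small_cohort():
    """Four mean(SD) trials plus one median-converted trial."""
    records = [
        make_record("T1", overall="high"),
        make_record("T2", overall="low"),
        make_record("T3", mean_a=75.0, sd_a=8.0, overall="low"),
        make_record("T4", mean_b=50.0, overall="high", domain1="unknown"),
        TrialRecord(
            trial_id="T5",
            variable_name="age",
            arm_a=RawSummary("median_iqr", 50.0, 40.0, 60.0, 80),
            arm_b=RawSummary("mean_sd", 49.0, 12.0, None, 78),
            rob2_overall="low",
            rob2_domain1="high",
        ),
    ]
    return CohortTable(records)
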
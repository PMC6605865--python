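import pytest

from immunoninf.trial_data import (
    AeRecord,
    AntigenSpec,
    Arm,
    RuleKind,
    SubjectRecord,
    default_antigen_panel,
)


@pytest.fixture(scope="session")
def panel():
    return default_antigen_panel()


@pytest.fixture(scope="session")
def spec_by_name(panel):
    return {s.name: s for s in panel}


def make_subject(
    subject_id="S-0",
    sub_cohort=1,
    arm=Arm.MMR_RIT,
    vaccinated=True,
    eligible=True,
    protocol_compliant=True,
    measurements=None,
    ae_records=None,
    country="USA",
):
    return SubjectRecord(
        subject_id=subject_id,
        sub_cohort=sub_cohort,
        arm=arm,
        country=country,
        age_years=4.5,
        vaccinated=vaccinated,
        eligible=eligible,
        protocol_compliant=protocol_compliant,
        measurements=measurements or {},
        ae_records=ae_records or [],
    )


@pytest.fixture
def small_trial():
    """Eight fully compliant subjects with measles results, 6:1:1 arms."""
    arms = [Arm.MMR_RIT] * 6 + [Arm.MMR_II_LOT1, Arm.MMR_II_LOT2]
    return [
        make_subject(
            subject_id=f"S-{i}",
            arm=arm,
            measurements={"measles": (2800.0, 4100.0 + i)},
        )
        for i, arm in enumerate(arms)
    ]
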
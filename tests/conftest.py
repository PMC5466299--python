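import pytest

from pzlesion import GeneratorParams, LesionRecord, Cohort, generate_cohort


def make_record(**overrides) -> LesionRecord:
    """A valid lesion record with overridable fields."""
    base = dict(
        patient_id="P1",
        reader_id="R1",
        s_t2=2,
        s_dw=3,
        s_dce=1,
        vol_t2=1.2,
        vol_dw=0.9,
        vol_dce=1.5,
        shape="nodular_no_mass_effect",
        ece_score=2,
        likert=4,
        dpsa=0.16,
        gleason_group=2,
        epe=False,
        excluded=False,
    )
    base.update(overrides)
    return LesionRecord(**base)


@pytest.fixture
def small_cohort() -> Cohort:
    """Three lesions over two patients, mixed outcomes."""
    return Cohort(
        (
            make_record(patient_id="P1", gleason_group=5, epe=True, likert=5),
            make_record(patient_id="P1", gleason_group=0, epe=False, likert=2,
                        s_t2=1, s_dw=1, s_dce=0, vol_t2=0.4, vol_dw=0.3,
                        vol_dce=None, shape="ill_defined"),
            make_record(patient_id="P2", gleason_group=2, epe=False, likert=3),
        ),
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """A mid-size synthetic cohort under default generator settings."""
    return generate_cohort(GeneratorParams(n_patients=250, seed=42))


@pytest.fixture(scope="session")
def big_frame_cohort() -> Cohort:
    """A large cohort for Monte-Carlo checks of marginal structure."""
    return generate_cohort(GeneratorParams(n_patients=6000, seed=7))
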
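import pytest

from bodycomp import AnthropometricMeasurement, Stage

# Printed cohort summaries used as worked-example inputs: per stage the
# mean weight (kg), TBW (kg), body density (g/mL), 2CM and 3CM mean TBF (%)
# and the reference FFM density (g/mL) used by the 2CM.
TABLE1 = {
    Stage.PRE_PREGNANCY: dict(
        weight=66.6, tbw=31.5, density=1.029, tbf2=31.4, tbf3=33.0, ffm_ref=1.100
    ),
    Stage.GW14: dict(
        weight=68.4, tbw=32.5, density=1.027, tbf2=31.8, tbf3=33.2, ffm_ref=1.099
    ),
    Stage.GW32: dict(
        weight=77.3, tbw=38.1, density=1.021, tbf2=32.7, tbf3=33.1, ffm_ref=1.092
    ),
    Stage.POSTPARTUM_2W: dict(
        weight=71.5, tbw=33.6, density=1.020, tbf2=33.8, tbf3=35.2, ffm_ref=1.094
    ),
}

# Printed per-stage FFM-density estimates (g/mL) from the 2CM inversion at
# the 3CM fat fraction.
FFM_DENSITY_ESTIMATES = {
    Stage.PRE_PREGNANCY: 1.106,
    Stage.GW14: 1.104,
    Stage.GW32: 1.093,
    Stage.POSTPARTUM_2W: 1.099,
}


@pytest.fixture
def stage_mean_measurements():
    """One measurement record per stage, at the printed cohort means."""
    return {
        stage: AnthropometricMeasurement(
            subject_id="means",
            stage=stage,
            body_weight=row["weight"],
            total_body_water=row["tbw"],
            body_density=row["density"],
        )
        for stage, row in TABLE1.items()
    }
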
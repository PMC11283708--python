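"""Shared test construction helpers."""

from ssbtax.demand import CohortStratum, Param


def make_stratum(ssb=300.0, juice=200.0, milk=150.0, **kw):
    defaults = dict(
        sex="male",
        age_lo=20,
        age_hi=24,
        population=1000.0,
        intake_ml_day={
            "ssb": Param(ssb, ssb * 0.07),
            "fruit_juice": Param(juice, juice * 0.07),
            "milk": Param(milk, milk * 0.07),
        },
        energy_kcal_day=2500.0,
        weight_kg=80.0,
        bmi_mean=26.0,
        bmi_sd=4.0,
    )
    defaults.update(kw)
    return CohortStratum(**defaults)
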
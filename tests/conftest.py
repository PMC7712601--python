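import numpy as np
import pytest

from ctebayes.cohort import Cohort, PatientRecord


def make_record(
    rid,
    age=30.0,
    sex="male",
    size=6.0,
    site="extremity",
    stage=3,
    surgery=1,
    rt=0,
    chemo=0,
    histology="spindle",
    time=24.0,
    event=1,
):
    return PatientRecord(
        id=rid, age=age, sex=sex, tumor_size_cm=size, site=site,
        seer_stage=stage, surgery=surgery, rt=rt, chemo=chemo,
        histology=histology, time_months=time, event=event,
    )


@pytest.fixture
def toy_cohort():
    """Six complete records, three per chemo arm, all in one stratum."""
    recs = [
        make_record("a", chemo=1, time=30.0, event=1),
        make_record("b", chemo=1, time=18.0, event=1),
        make_record("c", chemo=1, time=40.0, event=0),
        make_record("d", chemo=0, time=10.0, event=1),
        make_record("e", chemo=0, time=22.0, event=1),
        make_record("f", chemo=0, time=35.0, event=0),
    ]
    return Cohort(recs, provenance="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
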
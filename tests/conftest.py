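import numpy as np
import pytest

from vatpredict.cohort import SubjectRecord


def make_record(**overrides) -> SubjectRecord:
    """A fully populated male reference subject; override any field."""
    base = dict(
        subject_id="s1", sex="male", age=39.6, height=175.0, weight=81.2,
        wc=93.6, hc=103.4, sbp=122.0, dbp=80.0, glucose=88.6, tg=131.8,
        hdl=45.4, ldl=116.9, c_peptide=2.0, bp_treated=False,
        ct_vat=180.9, ct_sat=186.7,
    )
    base.update(overrides)
    return SubjectRecord(**base)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_records(rng, n):
    """Random physiologically plausible, fully populated records."""
    recs = []
    for i in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        height = rng.uniform(145, 200)
        bmi = rng.uniform(16, 45)
        recs.append(make_record(
            subject_id=f"r{i}", sex=sex, age=rng.uniform(20, 50),
            height=height, weight=bmi * (height / 100) ** 2,
            wc=rng.uniform(60, 150), hc=rng.uniform(75, 170),
            sbp=rng.uniform(90, 180), dbp=rng.uniform(50, 110),
            glucose=rng.uniform(65, 124), tg=rng.uniform(35, 500),
            hdl=rng.uniform(25, 110), c_peptide=rng.uniform(0.5, 6),
            ct_vat=rng.uniform(20, 400),
        ))
    return recs
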
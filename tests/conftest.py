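import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_meta(n_id=30, n_noid=14, n_flare=0, timepoints=("T0", "Tend"), seed=0):
    """Cohort metadata with the discovery study's structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, (mu, sd) in (
        ("ID", n_id, (9.91, 3.55)),
        ("NO_ID", n_noid, (13.42, 3.69)),
        ("FLARE", n_flare, (11.0, 3.5)),
    ):
        for i in range(n):
            subj = f"{group}{i:03d}"
            age = float(np.clip(rng.normal(mu, sd), 2, 18))
            sex = "F" if rng.random() < 0.7 else "M"
            for tp in timepoints:
                rows.append(
                    {
                        "sample_id": f"{subj}_{tp}",
                        "subject_id": subj,
                        "group": group,
                        "timepoint": tp,
                        "age": round(age, 2),
                        "sex": sex,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def meta_tend():
    """44 analysis samples at Tend (30 ID vs 14 NO_ID)."""
    m = make_meta()
    return m.loc[m.timepoint == "Tend"].reset_index(drop=True)


@pytest.fixture
def beta_fixture(rng):
    """Random 50-CpG x 10-sample beta matrix."""
    vals = rng.beta(2.0, 5.0, size=(50, 10))
    return pd.DataFrame(
        vals,
        index=[f"cg{i:05d}" for i in range(50)],
        columns=[f"s{i}" for i in range(10)],
    )
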
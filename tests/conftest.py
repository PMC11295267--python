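import pandas as pd
import pytest

import sihvalid as sv
from sihvalid.rulebook import CRITERION_NAMES
from sihvalid.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def rb():
    return sv.load_rulebook()


def zero_noise_config(**overrides) -> SimConfig:
    """Generator settings with every error process switched off."""
    base = dict(
        seed=7,
        n_hospitals_public=3,
        n_hospitals_private=3,
        episodes_per_hospital=80,
        record_sens={c: 1.0 for c in CRITERION_NAMES},
        record_false_pos={c: 0.0 for c in CRITERION_NAMES},
        p_undercapture={"public": 0.0, "private": 0.0},
        p_overcapture={"public": 0.0, "private": 0.0},
        p_key_corrupt={},
        p_split=0.4,
        p_background=0.0,
        p_reason_missing=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Full pipeline on a noise-free synthetic dataset (shared, read-only)."""
    sim = generate(zero_noise_config())
    result = sv.run_pipeline(
        sv.RunConfig(reduced=sim.reduced, acts=sim.acts, reference=sim.reference)
    )
    return sim, result


@pytest.fixture(scope="session")
def default_noise_run():
    """Pipeline on a dataset with the default error processes switched on."""
    cfg = SimConfig(seed=11, n_hospitals_public=5, n_hospitals_private=4,
                    episodes_per_hospital=120, p_split=0.1)
    sim = generate(cfg)
    result = sv.run_pipeline(
        sv.RunConfig(reduced=sim.reduced, acts=sim.acts, reference=sim.reference)
    )
    return sim, result


def make_aih(rb, **kw) -> dict:
    """One reduced-table row with sensible defaults, as a plain dict."""
    row = {f: None for f in rb.diagnosis_fields}
    row.update(
        aih_number=kw.pop("aih_number", "0000000000001"),
        cnes=kw.pop("cnes", "1000000"),
        aih_type=kw.pop("aih_type", 1),
        dob=pd.Timestamp(kw.pop("dob", "1990-05-01")),
        age=kw.pop("age", pd.NA),
        sex=kw.pop("sex", "F"),
        race_color=kw.pop("race_color", "1"),
        postcode=kw.pop("postcode", "12345678"),
        admission_date=pd.Timestamp(kw.pop("admission_date", "2021-11-10")),
        discharge_date=pd.Timestamp(kw.pop("discharge_date", "2021-11-12")),
        billing_reason=kw.pop("billing_reason", "1"),
        primary_procedure=kw.pop("primary_procedure", None),
        icu_days=kw.pop("icu_days", 0),
    )
    row.update(kw)  # remaining keys: diagnosis fields etc.
    return row


def frame(rb, rows) -> pd.DataFrame:
    return pd.DataFrame([make_aih(rb, **r) for r in rows])
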
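import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import idhscore as ih

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec():
    return ih.default_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """One default-size synthetic cohort (55 mut / 27 wt), fixed seed."""
    return ih.generate_cohort(spec, seed=20240418)


@pytest.fixture
def make_record():
    """Factory for fully specified patient records with overridable fields."""

    def factory(**overrides):
        base = dict(
            patient_id="p",
            idh_status="mut",
            age=35.0,
            male=False,
            single_lobe=True,
            multiple_lobes=False,
            insula=False,
            thalamus=False,
            corpus_callosum=False,
            contralateral=False,
            ventricle_adjacent=False,
            fa=0.15,
            md=1.50,
            met_tn=1.0,
            cho_tn=1.0,
            fdg_tn=0.5,
        )
        base.update(overrides)
        return ih.PatientRecord(**base)

    return factory


@pytest.fixture(scope="session")
def case1(request):
    """Representative astrocytoma: 34-year-old, insula invasion only."""
    return ih.PatientRecord(
        patient_id="case-1", idh_status="mut", age=34, male=True,
        single_lobe=True, multiple_lobes=False, insula=True, thalamus=False,
        corpus_callosum=False, contralateral=False, ventricle_adjacent=False,
        fa=0.16, md=1.53, met_tn=1.60, cho_tn=1.26, fdg_tn=0.76,
    )


@pytest.fixture(scope="session")
def case2(request):
    """Representative glioblastoma: 48-year-old, right frontal, no scored flags."""
    return ih.PatientRecord(
        patient_id="case-2", idh_status="wt", age=48, male=False,
        single_lobe=True, multiple_lobes=False, insula=False, thalamus=False,
        corpus_callosum=False, contralateral=False, ventricle_adjacent=False,
        fa=0.19, md=1.00, met_tn=4.78, cho_tn=2.77, fdg_tn=1.16,
    )


@pytest.fixture(scope="session")
def mega_spec(spec):
    """The default generative parameters at n=2000 per group (power checks)."""
    from dataclasses import replace

    return replace(spec, n_mut=2000, n_wt=2000)


def brute_force_auc(values, labels):
    """Independent pair-counting oracle for the wt-high empirical AUC."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    mut = values[labels == "mut"]
    wt = values[labels == "wt"]
    total = 0.0
    for w in wt:
        for m in mut:
            total += 1.0 if w > m else (0.5 if w == m else 0.0)
    return total / (len(wt) * len(mut))
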
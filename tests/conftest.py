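import numpy as np
import pandas as pd
import pytest

from painscope.datasets import MaskGeometry, StudyDataset
from painscope.preprocess import QuartileDataset
from painscope.simulate import GeneratorConfig, StudyDesign, \
    make_nested_parcellation, simulate_multistudy


def tiny_generator(scenario="MULTISYSTEM", n_studies=2, n_participants=8,
                   n_trials=12, **kwargs):
    """A very small corpus for unit tests: V = 216, 6 regions, 3 fRSN,
    2 cRSN."""
    designs = [
        StudyDesign(f"S{i + 1}", n_participants, n_trials,
                    (46.0, 47.0, 48.0), False, frozenset({"expectation"}), 0)
        for i in range(n_studies)
    ]
    base = dict(shape=(6, 6, 6), n_regions=6, n_frsn=3, n_crsn=2,
                n_pathway_regions=3, scenario=scenario, studies=designs,
                validation_studies=[])
    base.update(kwargs)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def tiny_corpus():
    gen = tiny_generator()
    datasets, truth = simulate_multistudy(gen, seed=11)
    return gen, datasets, truth


@pytest.fixture(scope="session")
def tiny_parcellation():
    return make_nested_parcellation(tiny_generator(), seed=3)


def null_quartiles(rng, n_participants=20, V=200, n_studies=1):
    """Pure-noise quartile data: features and ratings independent."""
    per = n_participants // n_studies
    rows_f, rows_m = [], []
    for s in range(n_studies):
        for p in range(per):
            pid = f"S{s + 1}_p{p:03d}"
            for q in range(1, 5):
                rows_f.append(rng.standard_normal(V))
                rows_m.append({"study_id": f"S{s + 1}",
                               "participant_id": pid, "quartile": q,
                               "rating": rng.standard_normal(),
                               "n_trials": 4})
    geo = MaskGeometry((1, 1, V), np.eye(4), np.arange(V))
    return QuartileDataset(geo, np.asarray(rows_f), pd.DataFrame(rows_m), [])


def simple_study(rng, n_participants=6, n_trials=8, V=50,
                 study_id="S1") -> StudyDataset:
    """Random-feature study with integer-ish ratings, for preprocessing
    tests."""
    n = n_participants * n_trials
    meta = pd.DataFrame({
        "participant_id": np.repeat(
            [f"{study_id}_p{i}" for i in range(n_participants)], n_trials),
        "trial_index": np.tile(np.arange(1, n_trials + 1), n_participants),
        "rating": rng.normal(50, 10, n),
        "temperature": rng.choice([46.0, 47.0, 48.0], n),
    })
    geo = MaskGeometry((1, 1, V), np.eye(4), np.arange(V))
    return StudyDataset(study_id, geo, rng.standard_normal((n, V)), meta)
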
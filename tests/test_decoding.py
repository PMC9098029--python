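import numpy as np
import pandas as pd
import pytest

from painscope._seeds import stage_rng
from painscope.datasets import AnalysisConfig
from painscope.decoding import (balance_participants, build_cv_scheme,
                                decode_studywise, grouped_folds,
                                nested_cv_predict, select_module, train_final)
from painscope.pcr import DimOptConfig
from painscope.preprocess import preprocess
from painscope.spaces import ModelSpace, build_model_spaces
from tests.conftest import null_quartiles


GRID = AnalysisConfig(dim_opt_method="grid")


@pytest.fixture(scope="module")
def tiny_qdata(tiny_corpus):
    _, datasets, _ = tiny_corpus
    return preprocess(datasets)


def test_cv_scheme_grouping_and_balance(tiny_qdata):
    scheme = build_cv_scheme(tiny_qdata.meta, repeats=2, folds=5, seed=1)
    meta = tiny_qdata.meta
    for r in range(2):
        for f, tr, te in scheme.outer_splits(r):
            assert not set(meta["participant_id"].iloc[tr]) & set(
                meta["participant_id"].iloc[te])
            counts = (meta.iloc[te][["study_id", "participant_id"]]
                      .drop_duplicates().groupby("study_id").size())
            if len(counts) > 1:
                assert counts.max() - counts.min() <= 1


def test_every_row_predicted_once_per_repeat(tiny_qdata):
    spaces = {"FULL": ModelSpace("FULL", "fixed",
                                 voxels=np.arange(tiny_qdata.features.shape[1]))}
    scheme = build_cv_scheme(tiny_qdata.meta, 2, 5, seed=2)
    ps = nested_cv_predict(tiny_qdata, spaces["FULL"], scheme, seed=2,
                           config=GRID)
    counts = ps.frame.groupby("row").size()
    assert (counts == 2).all()  # 2 repeats → each row tested exactly twice


def test_select_module_single_candidate(tiny_qdata):
    space = ModelSpace("REGION", "modular", modules=[np.arange(10)],
                       module_names=["only"])
    rng = stage_rng(0, "t")
    m = select_module(tiny_qdata.features, tiny_qdata.ratings, space,
                      tiny_qdata.meta["participant_id"].to_numpy(),
                      tiny_qdata.meta["study_id"].to_numpy(), 3,
                      DimOptConfig(method="grid"), rng)
    assert m == 0


def test_local_scenario_module_recovery(tiny_corpus):
    """With signal planted in one region, module selection finds it in at
    least 9 of 10 outer folds."""
    from tests.conftest import tiny_generator
    from painscope.simulate import simulate_multistudy
    gen = tiny_generator(scenario="LOCAL", n_participants=12)
    datasets, truth = simulate_multistudy(gen, seed=21)
    qdata = preprocess(datasets)
    spaces = build_model_spaces(truth.parcellation)
    scheme = build_cv_scheme(qdata.meta, 2, 5, seed=21)
    ps = nested_cv_predict(qdata, spaces["REGION"], scheme, seed=21,
                           config=GRID)
    truth_region = truth.signal_regions["pain"][0]
    truth_name = truth.parcellation.region_names[truth_region]
    hits = (ps.choices["module"] == truth_name).sum()
    assert hits >= 9, ps.choices


def test_train_final_reproduces_fitted_values(tiny_qdata):
    space = ModelSpace("FULL", "fixed",
                       voxels=np.arange(tiny_qdata.features.shape[1]))
    model = train_final(tiny_qdata, space, seed=3, config=GRID)
    pred = model.predict(tiny_qdata.features)
    again = model.predict(tiny_qdata.features)
    assert np.allclose(pred, again)
    assert np.isfinite(pred).all()


def test_frozen_model_transfers_to_holdout(tiny_corpus):
    """A model frozen on the training corpus achieves positive mean
    within-participant correlation on a new study from the same generator."""
    from tests.conftest import tiny_generator
    from painscope.simulate import simulate_multistudy
    from painscope.inference import participant_performance
    from painscope.decoding import PredictionSet
    from painscope.simulate import StudyDesign
    gen = tiny_generator(n_participants=12)
    gen.validation_studies = [
        StudyDesign("V1", 12, 12, (46.0, 47.0, 48.0), False,
                    frozenset({"expectation"}), 0)]
    datasets, truth = simulate_multistudy(gen, seed=31,
                                          include_validation=True)
    train_sets = [d for d in datasets if not d.study_id.startswith("V")]
    qdata = preprocess(train_sets)
    spaces = build_model_spaces(truth.parcellation)
    model = train_final(qdata, spaces["PATHWAYS"], seed=31, config=GRID)
    holdout = preprocess([d for d in datasets if d.study_id == "V1"])
    frame = holdout.meta.copy()
    frame["row"] = np.arange(len(frame))
    frame["repeat"] = 0
    frame["fold"] = 0
    frame["observed"] = holdout.ratings
    frame["predicted"] = model.predict(holdout.features)
    perf = participant_performance(
        PredictionSet("PATHWAYS", frame, pd.DataFrame()), "validation")
    assert perf["z"].mean() > 0


def test_balance_participants(tiny_qdata):
    sub = balance_participants(tiny_qdata, n_per_study=5, seed=0)
    counts = (sub.meta[["study_id", "participant_id"]].drop_duplicates()
              .groupby("study_id").size())
    assert (counts == 5).all()
    with pytest.raises(ValueError, match="balance"):
        balance_participants(tiny_qdata, n_per_study=999, seed=0)


def test_studywise_driver_trains_per_study(tiny_qdata):
    spaces = {"FULL": ModelSpace("FULL", "fixed",
                                 voxels=np.arange(tiny_qdata.features.shape[1]))}
    out = decode_studywise(tiny_qdata, spaces, GRID, seed=5)
    frame = out["FULL"].frame
    assert set(frame["study_id"]) == set(tiny_qdata.meta["study_id"])
    counts = frame.groupby("row").size()
    assert (counts == 2).all()


def test_grouped_folds_partition():
    rng = np.random.default_rng(0)
    pids = np.repeat([f"p{i}" for i in range(11)], 4)
    sids = np.repeat(["A"] * 6 + ["B"] * 5, 4)
    folds = grouped_folds(pids, sids, 5, rng)
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(44))
    for tr, te in folds:
        assert not set(pids[tr]) & set(pids[te])
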
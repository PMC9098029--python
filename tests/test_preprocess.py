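import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from painscope.datasets import MaskGeometry, StudyDataset
from painscope.preprocess import (preprocess, quartile_collapse,
                                  standardize_images, standardize_maps,
                                  zscore_ratings)
from tests.conftest import simple_study


def _study_from(features, ratings, study_id="S1", trials_per=None):
    n = len(ratings)
    trials_per = trials_per or n
    n_p = n // trials_per
    meta = pd.DataFrame({
        "participant_id": np.repeat([f"p{i}" for i in range(n_p)], trials_per),
        "trial_index": np.tile(np.arange(1, trials_per + 1), n_p),
        "rating": ratings,
    })
    V = features.shape[1]
    geo = MaskGeometry((1, 1, V), np.eye(4), np.arange(V))
    return StudyDataset(study_id, geo, features, meta)


def test_standardize_images_mean_zero_sd_one():
    rng = np.random.default_rng(0)
    ds = simple_study(rng, n_participants=5, n_trials=4, V=30)
    out = standardize_images([ds])[0]
    assert np.allclose(out.features.mean(axis=1), 0, atol=1e-10)
    assert np.allclose(out.features.std(axis=1), 1, atol=1e-10)
    # study mean map of output is generally NOT zero (per-image scaling)
    assert np.abs(out.features.mean(axis=0)).max() > 1e-6


def test_standardize_images_constant_image_errors():
    # two identical images are constant (zero) after study demeaning
    row = np.random.default_rng(0).standard_normal(10)
    ds = _study_from(np.vstack([row, row, row, row]), [1.0, 2, 3, 4])
    with pytest.raises(ValueError, match="zero-variance"):
        standardize_images([ds])


def test_standardize_maps_row_zscore():
    out = standardize_maps(np.array([[1.0, 2.0, 3.0]]))
    assert np.allclose(out.mean(axis=1), 0) and np.allclose(out.std(axis=1), 1)


def test_zscore_ratings_simple_and_errors():
    feats = np.random.default_rng(0).standard_normal((3, 5))
    ds = _study_from(feats, [1.0, 2.0, 3.0])
    out = zscore_ratings([ds])[0]
    assert np.allclose(out.ratings, [-1.0, 0.0, 1.0])  # sample SD (ddof=1)
    with pytest.raises(ValueError, match="constant"):
        zscore_ratings([_study_from(feats, [2.0, 2.0, 2.0])])


def test_zscore_per_study_not_pooled():
    rng = np.random.default_rng(1)
    a = simple_study(rng, study_id="A")
    b = simple_study(rng, study_id="B")
    b.meta["rating"] = b.meta["rating"] * 40 + 300  # different scale
    za, zb = zscore_ratings([a, b])
    for z in (za, zb):
        assert abs(z.ratings.mean()) < 1e-10
        assert abs(z.ratings.std(ddof=1) - 1) < 1e-10
    pooled = np.concatenate([za.ratings, zb.ratings])
    # per-study affine maps differ, so pooled SD is about 1 only by accident
    assert pooled.std(ddof=1) == pytest.approx(1.0, abs=0.2)


def test_quartile_binning_oracle():
    rng = np.random.default_rng(2)
    feats = rng.standard_normal((8, 6))
    ds = _study_from(feats, np.arange(1.0, 9.0))
    q = quartile_collapse([ds])
    assert list(q.meta["rating"]) == [1.5, 3.5, 5.5, 7.5]
    order = np.argsort(ds.ratings)
    for b in range(4):
        assert np.allclose(q.features[b], feats[order[2 * b:2 * b + 2]].mean(0))


def test_quartile_four_trials_identity():
    rng = np.random.default_rng(3)
    feats = rng.standard_normal((4, 5))
    ds = _study_from(feats, [3.0, 1.0, 4.0, 2.0])
    q = quartile_collapse([ds])
    order = np.argsort(ds.ratings)
    assert np.allclose(q.features, feats[order])
    assert list(q.meta["rating"]) == [1.0, 2.0, 3.0, 4.0]


def test_quartile_exclusions_logged_not_fatal():
    rng = np.random.default_rng(4)
    feats = rng.standard_normal((8, 5))
    ratings = np.array([0.0, 0, 0, 0, 1, 2, 3, 4])
    ds = _study_from(feats, ratings, trials_per=4)  # p0 constant ratings
    q = quartile_collapse([ds])
    assert q.participants == ["p1"]
    assert q.excluded == [("S1", "p0", "constant ratings")]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=5, max_size=24))
def test_quartile_ratings_monotone(ratings):
    ratings = np.asarray(ratings)
    if np.unique(ratings).size < 2:
        return
    feats = np.random.default_rng(0).standard_normal((len(ratings), 4))
    q = quartile_collapse([_study_from(feats, ratings)])
    r = q.meta["rating"].to_numpy()
    assert np.all(np.diff(r) >= -1e-12)


def test_full_pipeline_idempotent_ratings(tiny_corpus):
    _, datasets, _ = tiny_corpus
    q = preprocess(datasets)
    # ≤ 4 rows per participant, monotone in quartile
    for _, grp in q.meta.groupby("participant_id"):
        assert len(grp) <= 4
        assert np.all(np.diff(grp["rating"].to_numpy()) >= -1e-12)
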
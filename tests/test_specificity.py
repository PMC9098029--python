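import numpy as np
import pandas as pd
import pytest

from painscope.pcr import PCRModel
from painscope.simulate import simulate_specificity_maps, SPECIFICITY_TASKS
from painscope.specificity import (optimal_cutpoint, per_task_tests,
                                   score_task_maps, specificity_contrasts)


def _model(V, rng, intercept=0.0):
    return PCRModel(weights=rng.standard_normal(V), intercept=intercept,
                    k=1, column_means=np.zeros(V), voxels=np.arange(V))


def test_score_count_and_zero_map(tiny_corpus):
    gen, _, truth = tiny_corpus
    maps = simulate_specificity_maps(gen, seed=1, truth=truth)
    rng = np.random.default_rng(0)
    V = maps.features.shape[1]
    models = {"A": _model(V, rng), "B": _model(V, rng, intercept=2.0)}
    table = score_task_maps(models, maps)
    assert len(table) == maps.n_maps * 2
    # a zero map cannot be z-scored; score it unstandardized → intercept
    zero = maps.features[:1] * 0.0
    from painscope.pcr import apply_model
    assert apply_model(models["B"], zero)[0] == pytest.approx(2.0)


def test_scores_invariant_to_constant_shift(tiny_corpus):
    gen, _, truth = tiny_corpus
    maps = simulate_specificity_maps(gen, seed=2, truth=truth)
    rng = np.random.default_rng(1)
    model = {"m": _model(maps.features.shape[1], rng)}
    t1 = score_task_maps(model, maps)
    maps.features += 7.5  # constant offset removed by standardization
    t2 = score_task_maps(model, maps)
    assert np.allclose(t1["score"], t2["score"], atol=1e-8)


def test_matched_model_separates_pain_from_nonpain(tiny_corpus):
    gen, _, truth = tiny_corpus
    maps = simulate_specificity_maps(gen, seed=3, truth=truth)
    V = maps.features.shape[1]
    pain = truth.patterns["pain"]
    matched = {"pain_model": PCRModel(pain / np.linalg.norm(pain), 0.0, 1,
                                      np.zeros(V), np.arange(V))}
    table = score_task_maps(matched, maps)
    mean_pain = table.loc[table["category"] == "pain", "score"].mean()
    mean_non = table.loc[table["category"] != "pain", "score"].mean()
    assert mean_pain > mean_non
    contrasts = specificity_contrasts(table)
    row = contrasts.set_index("contrast").loc["pain_vs_nonpain"]
    assert row["estimate"] > 0 and row["p"] < 0.05


def test_null_pain_amplitude_contrast_covers_zero(tiny_corpus):
    gen, _, truth = tiny_corpus
    gen0 = gen.small(specificity_pain_amp={"heat": 0.0, "mechanical": 0.0,
                                           "visceral": 0.0})
    maps = simulate_specificity_maps(gen0, seed=4, truth=truth)
    V = maps.features.shape[1]
    pain = truth.patterns["pain"]
    matched = {"m": PCRModel(pain / np.linalg.norm(pain), 0.0, 1,
                             np.zeros(V), np.arange(V))}
    table = score_task_maps(matched, maps)
    row = specificity_contrasts(table).set_index("contrast").loc[
        "pain_vs_nonpain"]
    assert abs(row["estimate"]) < 2.5 * row["se"]


def test_per_task_tests_sidak():
    rng = np.random.default_rng(5)
    rows = []
    for task, cat, mod in SPECIFICITY_TASKS:
        for p in range(10):
            rows.append({"task": task, "category": cat,
                         "participant_id": f"{task}p{p}",
                         "score": rng.standard_normal()
                         + (3.0 if cat == "pain" else 0.0)})
    out = per_task_tests(pd.DataFrame(rows))
    sig = out.set_index("task")["significant"]
    assert all(sig[t] for t, c, _ in SPECIFICITY_TASKS if c == "pain")


def test_optimal_cutpoint_examples_and_degenerate():
    thr, sens, spec = optimal_cutpoint(np.array([1.0, 2, 3, 4]),
                                       np.array([0, 0, 1, 1]))
    assert thr == pytest.approx(2.5) and sens == 1.0 and spec == 1.0
    # perfectly separated
    thr, sens, spec = optimal_cutpoint(np.array([-5.0, -4, 4, 5]),
                                       np.array([0, 0, 1, 1]))
    assert sens == spec == 1.0
    # identical scores → chance: sens + spec = 1
    thr, sens, spec = optimal_cutpoint(np.ones(6),
                                       np.array([0, 0, 0, 1, 1, 1]))
    assert sens + spec == pytest.approx(1.0)
    with pytest.raises(ValueError, match="classes"):
        optimal_cutpoint(np.arange(4.0), np.ones(4))


def test_optimal_cutpoint_matches_exhaustive_scan():
    for i in range(50):
        rng = np.random.default_rng(i)
        scores = rng.standard_normal(25)
        labels = rng.integers(0, 2, 25)
        if labels.all() or not labels.any():
            continue
        thr, sens, spec = optimal_cutpoint(scores, labels)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        best = None
        uniq = np.sort(np.unique(scores))
        for t in np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                                 [uniq[-1] + 1]]):
            pred = scores > t
            s = (pred & (labels == 1)).sum() / n_pos
            c = (~pred & (labels == 0)).sum() / n_neg
            key = (abs(s - c), -(s + c))
            best = key if best is None or key < best else best
        assert (abs(sens - spec), -(sens + spec)) == best
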
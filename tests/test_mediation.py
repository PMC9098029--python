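import numpy as np
import pandas as pd
import pytest

from painscope.mediation import MediationModel, mediate, percent_mediated


def _orthogonalize(v, against):
    """Exact Gram-Schmidt residual (sample-orthogonal, mean-removed)."""
    v = v - v.mean()
    against = against - against.mean()
    return v - against * (v @ against) / (against @ against)


def _noiseless_system(rng, n_p=12, n_t=6):
    """X→M (α = 0.5), Y = 0.4·M + 0.3·X, with the mediator's independent
    variation constructed exactly orthogonal to X after within-participant
    demeaning — so every path is identified and exact."""
    pid = np.repeat(np.arange(n_p), n_t)
    demean = lambda v: v - pd.Series(v).groupby(pid).transform("mean").to_numpy()
    X = demean(rng.standard_normal(n_p * n_t))
    em = _orthogonalize(demean(rng.standard_normal(n_p * n_t)), X)
    M = 0.5 * X + em
    Y = 0.4 * M + 0.3 * X
    return X, M, Y, pid


def test_noiseless_paths_recovered_exactly():
    rng = np.random.default_rng(0)
    X, M, Y, pid = _noiseless_system(rng)
    res = mediate(pd.DataFrame({"x": X}), M, Y, pid, n_boot=20, seed=0)
    row = res.paths.iloc[0]
    assert row["alpha"] == pytest.approx(0.5, abs=1e-10)
    assert res.beta == pytest.approx(0.4, abs=1e-10)
    assert row["tau"] == pytest.approx(0.3, abs=1e-10)
    assert row["indirect"] == pytest.approx(0.2, abs=1e-10)
    assert row["total"] == pytest.approx(0.5, abs=1e-10)
    assert row["percent_mediated"] == 40


def test_total_effect_identity_any_data():
    rng = np.random.default_rng(1)
    n_p, n_t = 15, 5
    pid = np.repeat(np.arange(n_p), n_t)
    F = pd.DataFrame(rng.standard_normal((n_p * n_t, 3)),
                     columns=["a", "b", "c"])
    M = rng.standard_normal(n_p * n_t)
    Y = rng.standard_normal(n_p * n_t)
    res = mediate(F, M, Y, pid, n_boot=10, seed=1)
    # total ≡ factor coefficient in the outcome-only model, exactly
    model = MediationModel(F, M, Y, pid)
    tot = np.linalg.lstsq(model.F, model.y, rcond=None)[0]
    for j, (_, row) in enumerate(res.paths.iterrows()):
        assert row["total"] == pytest.approx(tot[j], abs=1e-10)
        assert row["total"] == pytest.approx(row["tau"] + row["indirect"],
                                             abs=1e-10)


def test_participant_label_shuffle_invariance():
    rng = np.random.default_rng(2)
    n_p, n_t = 10, 4
    pid = np.repeat([f"p{i}" for i in range(n_p)], n_t)
    F = pd.DataFrame({"x": rng.standard_normal(n_p * n_t)})
    M = rng.standard_normal(n_p * n_t)
    Y = rng.standard_normal(n_p * n_t)
    res1 = mediate(F, M, Y, pid, n_boot=10, seed=3)
    relabel = {f"p{i}": f"q{9 - i}" for i in range(n_p)}
    pid2 = np.array([relabel[p] for p in pid])
    res2 = mediate(F, M, Y, pid2, n_boot=10, seed=3)
    assert res1.paths["alpha"].iloc[0] == pytest.approx(
        res2.paths["alpha"].iloc[0], abs=1e-12)
    assert res1.paths["tau"].iloc[0] == pytest.approx(
        res2.paths["tau"].iloc[0], abs=1e-12)


def test_percent_mediated_arithmetic():
    rows = [(0.065, 0.471, 12), (0.2, 0.3, 40), (0.0, 0.5, 0)]
    for indirect, direct, expected in rows:
        paths = pd.DataFrame([{
            "factor": "f", "percent_mediated":
            round(100 * indirect / (indirect + direct))}])
        from painscope.mediation import _pct
        assert _pct(indirect, direct) == expected
    assert np.isnan(_pct(1e-14, -1e-14))


def test_constant_mediator_rejected():
    pid = np.repeat([0, 1, 2], 4)
    F = pd.DataFrame({"x": np.random.default_rng(0).standard_normal(12)})
    with pytest.raises(ValueError, match="constant mediator"):
        mediate(F, np.ones(12), np.arange(12.0), pid, n_boot=5)


def test_wedges_sum_to_model_r2():
    rng = np.random.default_rng(4)
    n_p, n_t = 20, 5
    pid = np.repeat(np.arange(n_p), n_t)
    F = pd.DataFrame(rng.standard_normal((n_p * n_t, 2)), columns=["a", "b"])
    M = F["a"].to_numpy() * 0.5 + rng.standard_normal(n_p * n_t)
    Y = 0.4 * M + 0.3 * F["b"].to_numpy() + rng.standard_normal(n_p * n_t)
    res = mediate(F, M, Y, pid, n_boot=10, seed=5)
    assert res.wedges["share"].sum() == pytest.approx(res.model_r2,
                                                      abs=1e-10)
    assert (res.wedges["share"] >= -1e-12).all()
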
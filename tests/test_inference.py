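import numpy as np
import pandas as pd
import pytest

from painscope.inference import (bayes_factor_null, calibration_check,
                                 compare_spaces, fisher_z,
                                 participant_performance, planned_contrasts,
                                 screen_modules, sidak_level)
from painscope.decoding import PredictionSet
from painscope.spaces import SPACE_IDS


def _predset(frame, space="FULL"):
    return PredictionSet(space, frame, pd.DataFrame())


def _frame(pred, obs, pid, study="S1"):
    n = len(pred)
    return pd.DataFrame({"row": np.arange(n), "repeat": 0, "fold": 0,
                         "participant_id": pid, "study_id": study,
                         "observed": obs, "predicted": pred})


def test_fisher_z_values_and_clipping():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
    assert np.isfinite(fisher_z(1.0))
    assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-6))
    # odd and monotone; inverse recovers r inside the clip range
    r = np.linspace(-0.99, 0.99, 21)
    z = fisher_z(r)
    assert np.allclose(np.tanh(z), r, atol=1e-12)
    assert np.all(np.diff(z) > 0)
    assert np.allclose(fisher_z(-r), -z)


def test_participant_performance_perfect_and_degenerate():
    pid = np.repeat(["a", "b"], 4)
    obs = np.tile([1.0, 2, 3, 4], 2)
    perf = participant_performance(_predset(_frame(obs, obs, pid)))
    assert np.allclose(perf["z"], np.arctanh(1 - 1e-6))
    flat = participant_performance(
        _predset(_frame(np.zeros(8), obs, pid)))
    assert flat["z"].isna().all()


def test_sidak_levels():
    assert sidak_level(0.05, 1) == pytest.approx(0.05)
    assert sidak_level(0.05, 486) == pytest.approx(1.0546e-4, rel=1e-3)


def test_planned_contrasts_orthogonal():
    codes = list(planned_contrasts().values())
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            assert abs(codes[i] @ codes[j]) < 1e-12
        assert abs(codes[i].sum()) < 1e-12


def _perf_table(rng, n_studies=8, n_per=12, mu=None, study_sd=0.15,
                slope_sd=0.08, participant_sd=0.3, resid_sd=0.4):
    mu = mu or {sp: 0.5 for sp in SPACE_IDS}
    rows = []
    for s in range(n_studies):
        u_s = rng.normal(0, study_sd)
        slopes = {sp: rng.normal(0, slope_sd) for sp in SPACE_IDS}
        for p in range(n_per):
            u_p = rng.normal(0, participant_sd)
            for sp in SPACE_IDS:
                rows.append({"participant_id": f"s{s}p{p}",
                             "study_id": f"st{s}", "space": sp,
                             "z": mu[sp] + u_s + u_p + slopes[sp]
                             + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


def test_identical_spaces_zero_contrast():
    rng = np.random.default_rng(0)
    table = _perf_table(rng, slope_sd=0.0)
    # make CRSN and FRSN columns literally identical
    wide = table.pivot_table(index=["participant_id", "study_id"],
                             columns="space", values="z").reset_index()
    wide["CRSN"] = wide["FRSN"]
    table = wide.melt(id_vars=["participant_id", "study_id"],
                      var_name="space", value_name="z")
    comp = compare_spaces(table)
    c3 = comp.contrasts.set_index("contrast").loc["C3_crsn_vs_frsn"]
    assert c3["estimate"] == pytest.approx(0.0, abs=1e-10)


def test_planted_offset_recovered():
    rng = np.random.default_rng(1)
    mu = {sp: (0.8 if sp in ("PATHWAYS", "META", "FULL") else 0.5)
          for sp in SPACE_IDS}
    table = _perf_table(rng, mu=mu)
    comp = compare_spaces(table)
    c1 = comp.contrasts.set_index("contrast").loc["C1_distributed_vs_modular"]
    assert c1["estimate"] == pytest.approx(0.3, abs=3 * c1["se"])
    assert c1["p"] < 0.05
    omnibus = comp.overall_test()
    assert omnibus["df_num"] == 5 and omnibus["p"] < 0.05


def test_bayes_factor_null_direction():
    rng = np.random.default_rng(2)
    null_tab = _perf_table(rng, n_studies=10, n_per=16, slope_sd=0.02)
    bf_null = bayes_factor_null(null_tab, "C1_distributed_vs_modular")
    mu = {sp: (1.2 if sp in ("PATHWAYS", "META", "FULL") else 0.5)
          for sp in SPACE_IDS}
    eff_tab = _perf_table(rng, n_studies=10, n_per=16, mu=mu, slope_sd=0.02)
    bf_eff = bayes_factor_null(eff_tab, "C1_distributed_vs_modular")
    assert bf_null > 1.0  # evidence for the null under the null
    assert bf_eff < 1.0   # evidence against the null under a large effect
    # not invariant to pseudo-replication
    dup = pd.concat([null_tab, null_tab], ignore_index=True)
    dup["participant_id"] = dup["participant_id"] + np.repeat(
        ["", "_copy"], len(null_tab))
    assert bayes_factor_null(dup, "C1_distributed_vs_modular") != pytest.approx(
        bf_null, rel=1e-6)


def test_calibration_degenerate_interval_collapses():
    rng = np.random.default_rng(3)
    table = _perf_table(rng, study_sd=1e-4, slope_sd=1e-4,
                        participant_sd=1e-4, resid_sd=1e-3)
    comp = compare_spaces(table)
    hold = _perf_table(rng, n_studies=1, study_sd=1e-4, slope_sd=1e-4,
                       participant_sd=1e-4, resid_sd=1e-3)
    hold["study_id"] = "H0"
    rep = calibration_check(comp, hold)
    widths = rep["upper"] - rep["lower"]
    assert (widths < 0.05).all()  # variance terms ≈ 0 → ± t·SE only


def test_screening_flags_signal_not_noise():
    rng = np.random.default_rng(4)
    pid = np.repeat([f"p{i}" for i in range(20)], 4)
    obs = rng.standard_normal(80)
    good = obs + 0.3 * rng.standard_normal(80)
    noise = rng.standard_normal(80)
    table = screen_modules({
        "signal": _predset(_frame(good, obs, pid), "signal"),
        "noise": _predset(_frame(noise, obs, pid), "noise"),
    }, alpha=0.05)
    res = table.set_index("module")
    assert bool(res.loc["signal", "significant"])
    assert not bool(res.loc["noise", "significant"])
    assert table.attrs["sidak_level"] == pytest.approx(
        sidak_level(0.05, 2))
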
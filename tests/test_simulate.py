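import numpy as np
import pytest

from painscope.simulate import (GeneratorConfig, make_nested_parcellation,
                                simulate_multistudy,
                                simulate_specificity_maps, SPECIFICITY_TASKS)
from tests.conftest import tiny_generator


def test_parcellation_partitions_and_nests(tiny_parcellation):
    parc = tiny_parcellation
    V = parc.geometry.n_voxels
    assert sum(parc.label_counts().values()) == V
    # nesting maps are total functions
    for r in parc.region_labels:
        assert parc.region_frsn[r] in parc.frsn_crsn
    # each region's voxels form one connected-ish Voronoi cell: at minimum
    # nonempty
    assert all(c > 0 for c in parc.label_counts().values())


def test_meta_mask_fraction(tiny_parcellation):
    # the meta mask grows from the pathway set to ≈ the target fraction,
    # overshooting by at most one region
    parc = tiny_parcellation
    V = parc.geometry.n_voxels
    counts = parc.label_counts()
    frac = parc.meta_mask().mean()
    pathway_frac = sum(counts[r] for r in parc.pathway_regions) / V
    biggest = max(counts.values()) / V
    assert max(0.30, pathway_frac) - 1e-9 <= frac
    assert frac <= max(0.30, pathway_frac) + biggest


def test_degenerate_single_module_parcellation():
    gen = tiny_generator(n_regions=1, n_frsn=1, n_crsn=1,
                         n_pathway_regions=1)
    parc = make_nested_parcellation(gen, seed=0)
    assert parc.region_labels == [1]
    assert len(parc.frsn_names) == 1 and len(parc.crsn_names) == 1


def test_zero_coefficient_zero_noise_ratings_constant():
    gen = tiny_generator(b_temp=0, b_expectation=0, b_social=0, b_control=0,
                         b_habituation=0, participant_sd=0, unique_sd=0,
                         rating_noise_sd=0)
    datasets, _ = simulate_multistudy(gen, seed=0)
    for ds in datasets:
        assert np.allclose(ds.ratings, ds.ratings[0])


def test_rating_model_coefficient_recovery():
    """OLS on standardized regressors recovers each configured b within
    3 standard errors (large-n regression oracle)."""
    gen = tiny_generator(n_studies=1, n_participants=40, n_trials=60,
                         scenario="GLOBAL")
    datasets, truth = simulate_multistudy(gen, seed=5)
    ds = datasets[0]
    b_true = truth.coefficients[ds.study_id]
    m = ds.meta
    z = lambda v: (v - v.mean()) / v.std()
    X = np.column_stack([
        z(m["temperature"]), z(m["expectation"]),
        z(m.groupby("participant_id").cumcount().astype(float)),
    ])
    # absorb participant intercepts
    import pandas as pd
    pid = m["participant_id"]
    Xd = X - pd.DataFrame(X).groupby(pid.values).transform("mean").to_numpy()
    yd = (ds.ratings
          - pd.Series(ds.ratings).groupby(pid.values).transform("mean")
          .to_numpy())
    coef, _, _, _ = np.linalg.lstsq(Xd, yd, rcond=None)
    resid = yd - Xd @ coef
    sigma2 = resid @ resid / (len(yd) - 40 - 3)
    se = np.sqrt(np.diag(np.linalg.inv(Xd.T @ Xd)) * sigma2)
    expected = [b_true["temperature"], b_true["expectation"],
                b_true["habituation"]]
    for c, e, s in zip(coef, expected, se):
        assert abs(c - e) < 3 * s


def test_local_patterns_confined_to_one_region():
    gen = tiny_generator(scenario="LOCAL")
    _, truth = simulate_multistudy(gen, seed=7)
    channels = [c for c in truth.signal_regions if c != "salience"]
    regions = {r for c in channels for r in truth.signal_regions[c]}
    assert len(regions) == 1
    region = regions.pop()
    outside = truth.parcellation.voxel_regions != region
    for name in channels:
        assert np.all(truth.patterns[name][outside] == 0.0)


def test_scenario_scope_invariants():
    for scenario, check in [
        ("MULTISYSTEM", lambda parc, regs: len(regs) >= 3 and len(
            {parc.frsn_crsn[parc.region_frsn[r]] for r in regs}) >= 2),
        ("GLOBAL", lambda parc, regs: len(regs) >= len(
            parc.region_labels) / 2),
    ]:
        gen = tiny_generator(scenario=scenario)
        _, truth = simulate_multistudy(gen, seed=3)
        regions = sorted({r for c, regs in truth.signal_regions.items()
                          if c != "salience" for r in regs})
        assert check(truth.parcellation, regions), scenario


def test_cue_uncorrelated_with_temperature():
    gen = tiny_generator(n_studies=1, n_participants=40, n_trials=60)
    datasets, _ = simulate_multistudy(gen, seed=9)
    m = datasets[0].meta
    r = np.corrcoef(m["temperature"], m["expectation"])[0, 1]
    assert abs(r) < 0.1  # |corr| shrinks with n; n = 2400 here


def test_specificity_map_counts_and_ordering(tiny_corpus):
    gen, _, truth = tiny_corpus
    maps = simulate_specificity_maps(gen, seed=2, truth=truth)
    assert maps.n_maps == len(SPECIFICITY_TASKS) * gen.n_specificity_participants
    # heat amplitude > visceral amplitude → higher mean matched-filter score
    pain = truth.patterns["pain"]
    scores = maps.features @ (pain / np.linalg.norm(pain))
    meta = maps.meta
    heat = scores[(meta["modality"] == "heat").to_numpy()].mean()
    visc = scores[(meta["modality"] == "visceral").to_numpy()].mean()
    nonpain = scores[(meta["category"] != "pain").to_numpy()].mean()
    assert heat > visc > nonpain


def test_generator_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_regions=2, n_frsn=4, n_crsn=1)
    with pytest.raises(ValueError):
        GeneratorConfig(meta_fraction=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(scenario="EVERYWHERE")
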
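"""Synthetic multi-study corpus generator with configurable signal scope.

The generator emulates a corpus of thermal-pain fMRI studies: each study has
its own participant count, trial count, stimulus-temperature design and set of
psychological manipulations (predictive cues, social context, perceived
control), habituation across trials, participant-specific rating offsets, and
study-specific image offsets and amplitudes.  Trial images carry factor-locked
spatial patterns plus a rating-locked "unique variance" pattern, with
parcel-structured noise.  The spatial scope of all signal patterns — one
region (LOCAL), several regions across coarse networks (MULTISYSTEM), or most
of the brain (GLOBAL) — is configurable ground truth, so spatial-scope
recovery by the decoding stage can be tested against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .datasets import MaskGeometry, StudyDataset
from .spaces import Parcellation

__all__ = [
    "StudyDesign",
    "GeneratorConfig",
    "GroundTruth",
    "TaskMapSet",
    "make_nested_parcellation",
    "simulate_multistudy",
    "simulate_specificity_maps",
    "paper_corpus_designs",
    "validation_corpus_designs",
]

SCENARIOS = ("LOCAL", "MULTISYSTEM", "GLOBAL")

#: task roster for the specificity dataset: 6 pain, 6 cognitive-demand,
#: 6 aversive-affect tasks
SPECIFICITY_TASKS = [
    ("heat_1", "pain", "heat"), ("heat_2", "pain", "heat"),
    ("mechanical_1", "pain", "mechanical"), ("mechanical_2", "pain", "mechanical"),
    ("visceral_1", "pain", "visceral"), ("visceral_2", "pain", "visceral"),
    ("wm_1", "cognitive", None), ("wm_2", "cognitive", None),
    ("inhibition_1", "cognitive", None), ("inhibition_2", "cognitive", None),
    ("conflict_1", "cognitive", None), ("conflict_2", "cognitive", None),
    ("aversive_img_1", "aversive", None), ("aversive_img_2", "aversive", None),
    ("rejection", "aversive", None), ("vicarious_pain", "aversive", None),
    ("aversive_sound_1", "aversive", None), ("aversive_sound_2", "aversive", None),
]


@dataclass(frozen=True)
class StudyDesign:
    """One study's behavioral design.

    ``temperatures`` is either a tuple of discrete stimulus levels (°C) or a
    ``(low, high)`` continuous range flagged by ``continuous_temp``; a single
    level means temperature is constant and contributes no rating variance.
    ``factors`` lists the psychological manipulations present.
    """

    study_id: str
    n_participants: int
    n_trials: int
    temperatures: tuple[float, ...] = (46.0, 47.0, 48.0)
    continuous_temp: bool = False
    factors: frozenset[str] = frozenset({"expectation"})
    site: int = 0  # stimulation site code


def paper_corpus_designs() -> list[StudyDesign]:
    """The seven-study training corpus (participant/trial counts and
    manipulations mirroring a multi-study thermal-pain archive)."""
    F = frozenset
    return [
        StudyDesign("S1", 28, 81, (46.0, 47.0, 48.0), False, F({"expectation"}), 0),
        StudyDesign("S2", 17, 64, (41.1, 44.2, 47.1), False, F({"expectation"}), 0),
        StudyDesign("S3", 16, 70, (48.0, 49.0), False, F({"expectation"}), 0),
        StudyDesign("S4", 29, 64, (45.0, 47.0), False,
                    F({"expectation", "control"}), 0),
        StudyDesign("S5", 26, 48, (40.8, 47.0), True, F(), 0),
        StudyDesign("S6", 30, 16, (47.0,), False, F({"social"}), 0),
        StudyDesign("S7", 25, 96, (48.0, 49.0, 50.0), False,
                    F({"expectation", "social"}), 1),
    ]


def validation_corpus_designs() -> list[StudyDesign]:
    """Four held-out validation studies."""
    F = frozenset
    return [
        StudyDesign("V1", 33, 97, (44.3, 45.3, 46.3, 47.3, 48.3, 49.3),
                    False, F({"expectation"}), 0),
        StudyDesign("V2", 45, 48, (46.0, 47.0, 48.0), False, F({"expectation"}), 0),
        StudyDesign("V3", 40, 60, (46.4,), False, F({"expectation"}), 0),
        StudyDesign("V4", 87, 36, (47.0, 48.0, 49.0), False, F(), 0),
    ]


@dataclass
class GeneratorConfig:
    """All generator knobs: corpus layout, parcellation sizes, factor
    coefficients (standardized rating units), signal scope and noise model."""

    shape: tuple[int, int, int] = (12, 12, 14)
    n_regions: int = 24
    n_frsn: int = 8
    n_crsn: int = 4
    n_pathway_regions: int = 6
    meta_fraction: float = 0.30
    scenario: str = "MULTISYSTEM"
    studies: list[StudyDesign] = field(default_factory=paper_corpus_designs)
    validation_studies: list[StudyDesign] = field(
        default_factory=validation_corpus_designs)
    # rating model (standardized regressor units)
    b_temp: float = 0.30
    b_expectation: float = 0.25
    b_social: float = 0.25
    b_control: float = -0.20
    b_habituation: float = -0.25
    participant_sd: float = 0.80
    unique_sd: float = 0.35        # rating noise the brain encodes (ε_brain)
    rating_noise_sd: float = 1.00  # report noise absent from the brain
    study_coefficients: dict = field(default_factory=dict)  # per-study overrides
    # image model; noise variance splits into a few global spatial modes
    # (motion/physiology-like), a parcel-shared residual, and voxel white
    # noise — shares sum to ≤ 1, the remainder is white
    pattern_amp: float = 7.0
    unique_gain: float = 1.0
    image_noise_sd: float = 1.0
    n_noise_modes: int = 4
    noise_global_share: float = 0.85
    noise_parcel_share: float = 0.05
    study_offset_sd: float = 0.50
    study_amp_sd: float = 0.10
    # nonspecific salience/arousal channel: a global pattern, partially
    # rating-correlated during pain runs and evoked by every task
    salience_image_amp: float = 0.0     # training images, × pattern_amp
    salience_rating_corr: float = 0.0   # corr of its drive with the
                                        # decodable rating signal
    # specificity maps
    specificity_pain_amp: dict = field(default_factory=lambda: {
        "heat": 1.0, "mechanical": 0.7, "visceral": 0.6})
    salience_amp: float = 0.5
    salience_map_jitter: float = 0.5    # per-map arousal variability
    task_amp: float = 0.5
    map_noise_sd: float = 0.15  # per-voxel; ≈ trial-averaged single-trial noise
    n_specificity_participants: int = 15

    def __post_init__(self):
        if not (self.n_regions >= self.n_frsn >= self.n_crsn >= 1):
            raise ValueError("need n_regions ≥ n_frsn ≥ n_crsn ≥ 1")
        if not 0.0 < self.meta_fraction < 1.0:
            raise ValueError("meta_fraction must lie in (0, 1)")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if (min(self.noise_global_share, self.noise_parcel_share) < 0
                or self.noise_global_share + self.noise_parcel_share > 1):
            raise ValueError("noise shares must be ≥ 0 and sum to ≤ 1")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coefficients_for(self, study_id: str) -> dict[str, float]:
        base = {
            "temperature": self.b_temp,
            "expectation": self.b_expectation,
            "social": self.b_social,
            "control": self.b_control,
            "habituation": self.b_habituation,
        }
        base.update(self.study_coefficients.get(study_id, {}))
        return base

    def small(self, **kwargs) -> "GeneratorConfig":
        """Convenience: a reduced copy for quick runs (same structure)."""
        return replace(self, **kwargs)

    @classmethod
    def desk_scale(cls, scenario: str = "MULTISYSTEM",
                   n_studies: int = 3, n_participants: int = 30,
                   n_trials: int = 16, **kwargs) -> "GeneratorConfig":
        """A reduced corpus for simulation studies: V = 1000 voxels, 20
        regions nested in 8 fine and 4 coarse networks, 6 pathway regions,
        and homogeneous studies (identical designs, small amplitude
        heterogeneity).  Signal and noise parameters are the calibrated
        defaults."""
        designs = [
            StudyDesign(f"S{i + 1}", n_participants, n_trials,
                        (46.0, 47.0, 48.0), False,
                        frozenset({"expectation"}), 0)
            for i in range(n_studies)
        ]
        base = dict(
            shape=(10, 10, 10), n_regions=20, n_frsn=8, n_crsn=4,
            n_pathway_regions=6, scenario=scenario, studies=designs,
            validation_studies=[], study_amp_sd=0.05,
        )
        base.update(kwargs)
        return cls(**base)


@dataclass
class GroundTruth:
    """What the generator planted: spatial patterns per factor, the regions
    carrying them, and the true rating coefficients per study."""

    scenario: str
    parcellation: Parcellation
    patterns: dict[str, np.ndarray]       # factor (and 'pain') → length-V vector
    signal_regions: dict[str, list[int]]  # factor → region labels with signal
    coefficients: dict[str, dict[str, float]]  # study → factor → b


# ----------------------------------------------------------------------
# parcellation


def make_nested_parcellation(cfg: GeneratorConfig, seed: int) -> Parcellation:
    """Grow a nested parcellation of contiguous regions on the grid.

    Regions are discrete Voronoi cells around random seed voxels; regions are
    grouped into fRSNs (and fRSNs into cRSNs) by nearest seed centroid, so the
    three scales nest exactly.  The pathway set is a random region subset
    spanning ≥ 2 cRSNs (when possible); the meta mask is the union of the
    pathway regions plus further regions until ≈ ``meta_fraction`` of voxels
    is covered.
    """
    V = cfg.n_voxels
    if cfg.n_regions > V:
        raise ValueError(f"cannot fit {cfg.n_regions} regions in {V} voxels")
    rng = stage_rng(seed, "parcellation")
    grid = np.indices(cfg.shape).reshape(3, -1).T.astype(float)

    def _nearest(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
        d = ((points[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
        return d.argmin(1)

    seed_idx = rng.choice(V, size=cfg.n_regions, replace=False)
    assign = _nearest(grid, grid[seed_idx])  # 0-based region index per voxel
    # relabel so every region is nonempty (Voronoi of its own seed ⇒ nonempty)
    labels = assign + 1
    region_labels = list(range(1, cfg.n_regions + 1))
    centroids = np.stack([grid[labels == r].mean(0) for r in region_labels])

    frsn_seed = rng.choice(cfg.n_regions, size=cfg.n_frsn, replace=False)
    frsn_of_region = _nearest(centroids, centroids[frsn_seed])
    frsn_names = [f"fRSN{j + 1:02d}" for j in range(cfg.n_frsn)]
    frsn_centroids = np.stack([
        centroids[frsn_of_region == j].mean(0) for j in range(cfg.n_frsn)])
    crsn_seed = rng.choice(cfg.n_frsn, size=cfg.n_crsn, replace=False)
    crsn_of_frsn = _nearest(frsn_centroids, frsn_centroids[crsn_seed])
    crsn_names = [f"cRSN{j + 1}" for j in range(cfg.n_crsn)]

    region_frsn = {r: frsn_names[frsn_of_region[i]]
                   for i, r in enumerate(region_labels)}
    frsn_crsn = {frsn_names[j]: crsn_names[crsn_of_frsn[j]]
                 for j in range(cfg.n_frsn)}

    # pathway subset spanning ≥2 cRSNs where the parcellation allows it
    n_path = min(cfg.n_pathway_regions, cfg.n_regions)
    for _ in range(200):
        path = sorted(rng.choice(region_labels, size=n_path, replace=False))
        crsns = {frsn_crsn[region_frsn[r]] for r in path}
        if len(crsns) >= min(2, cfg.n_crsn) or n_path == cfg.n_regions:
            break
    pathway = set(int(r) for r in path)

    counts = np.bincount(labels, minlength=cfg.n_regions + 1)
    target = cfg.meta_fraction * V
    meta = set(pathway)
    covered = sum(counts[r] for r in meta)
    order = [r for r in rng.permutation(region_labels) if r not in meta]
    for r in order:
        if covered >= target:
            break
        meta.add(int(r))
        covered += counts[r]

    geometry = MaskGeometry(tuple(cfg.shape), np.diag([2.0, 2.0, 2.0, 1.0]),
                            np.arange(V))
    return Parcellation(
        geometry=geometry,
        voxel_regions=labels,
        region_names={r: f"R{r:03d}" for r in region_labels},
        region_frsn=region_frsn,
        frsn_crsn=frsn_crsn,
        pathway_regions=pathway,
        meta_regions=meta,
    )


# ----------------------------------------------------------------------
# multistudy simulation


def _scenario_regions(cfg: GeneratorConfig, parc: Parcellation,
                      rng: np.random.Generator) -> list[int]:
    """Pick the signal-bearing regions for the configured scope."""
    labels = parc.region_labels
    if cfg.scenario == "LOCAL":
        pool = sorted(parc.pathway_regions) or labels
        return [int(rng.choice(pool))]
    if cfg.scenario == "MULTISYSTEM":
        # the nociceptive-pathway subset: ≥3 regions across ≥2 coarse networks
        chosen = sorted(parc.pathway_regions)
        if len(chosen) < 3:
            extra = [r for r in labels if r not in chosen]
            chosen += [int(r) for r in
                       rng.choice(extra, size=3 - len(chosen), replace=False)]
        return sorted(chosen)
    n = max(int(math.ceil(0.5 * len(labels))), 1)
    return sorted(int(r) for r in rng.choice(labels, size=n, replace=False))


def _make_pattern(parc: Parcellation, regions: list[int],
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-norm random spatial pattern supported on the given regions."""
    support = np.isin(parc.voxel_regions, regions)
    vec = np.zeros(parc.geometry.n_voxels)
    vec[support] = rng.standard_normal(int(support.sum()))
    nrm = np.linalg.norm(vec)
    if nrm > 0:
        vec /= nrm
    return vec


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_multistudy(cfg: GeneratorConfig, seed: int,
                        parcellation: Parcellation | None = None,
                        include_validation: bool = False,
                        ) -> tuple[list[StudyDataset], GroundTruth]:
    """Generate the multi-study corpus plus its ground truth.

    Rating model (standardized regressor units)::

        rating_i = Σ_f b_f · x_{f,i} + u_participant + ε_brain,i + ε_report,i

    Image model::

        image_i = Σ_f b_f · x_{f,i} · pattern_f
                  + unique_gain · ε_brain,i · pattern_pain
                  + parcel-correlated noise + study offset map

    scaled per study by ``1 + N(0, study_amp_sd)``.  The ε_brain term gives
    the images rating-correlated variance beyond the manipulated factors (a
    decoder can capture unique rating variance); ε_report is report noise no
    decoder can reach, setting a common performance ceiling.  Each factor's
    pattern is confined to its own subset of the scenario's signal regions
    (LOCAL: all factors share the single region), so in distributed
    scenarios no single region carries the whole decodable signal — the
    different influences on pain live in different systems and only
    multisystem or full-brain decoders can integrate them.  Cue regressors
    are drawn independently of stimulus intensity, habituation is linear in
    trial index, and the factor set respects each study's schema.
    """
    parc = parcellation or make_nested_parcellation(cfg, seed)
    rng = stage_rng(seed, "multistudy")
    regions = _scenario_regions(cfg, parc, rng)

    factor_names = ["temperature", "expectation", "social", "control",
                    "habituation"]
    channels = factor_names + ["pain"]
    # deal signal regions round-robin over channels: every chosen region
    # carries signal, and in distributed scenarios channels segregate
    assign: dict[str, list[int]] = {ch: [] for ch in channels}
    if len(regions) == 1:
        for ch in channels:
            assign[ch] = list(regions)
    else:
        order = list(rng.permutation(factor_names))
        for i, r in enumerate(regions):
            assign[order[i % len(order)]].append(int(r))
        for ch in factor_names:  # a factor left empty shares the first set
            if not assign[ch]:
                assign[ch] = list(assign[order[0]])
        # the pain-specific (unique-variance) pattern is itself distributed:
        # it spans half of the signal regions, spread across coarse networks
        # so that no single module covers most of it
        by_crsn: dict[str, list[int]] = {}
        for r in regions:
            by_crsn.setdefault(parc.frsn_crsn[parc.region_frsn[r]],
                               []).append(int(r))
        n_pain = max(2, int(math.ceil(len(regions) / 2)))
        pain_regions: list[int] = []
        pools = [list(rng.permutation(v)) for v in by_crsn.values()]
        while len(pain_regions) < n_pain and any(pools):
            for pool in pools:
                if pool and len(pain_regions) < n_pain:
                    pain_regions.append(int(pool.pop()))
        assign["pain"] = sorted(pain_regions)
    patterns = {ch: cfg.pattern_amp * _make_pattern(parc, assign[ch], rng)
                for ch in channels}
    signal_regions = {ch: sorted(assign[ch]) for ch in channels}
    # global nonspecific salience pattern, shared with the task-map set
    patterns["salience"] = (cfg.pattern_amp * cfg.salience_image_amp
                            * _make_pattern(parc, parc.region_labels, rng))
    signal_regions["salience"] = list(parc.region_labels)

    designs = list(cfg.studies) + (list(cfg.validation_studies)
                                   if include_validation else [])
    datasets, coefficients = [], {}
    V = parc.geometry.n_voxels
    parcel_index = parc.voxel_regions  # labels per voxel
    unique_parcels = np.unique(parcel_index)
    parcel_pos = np.searchsorted(unique_parcels, parcel_index)
    # global noise modes shared by the whole corpus (same physiological
    # structure in every study); per-voxel variance 1
    q = max(cfg.n_noise_modes, 1)
    modes = rng.standard_normal((q, V)) / math.sqrt(q)
    s_g, s_p = cfg.noise_global_share, cfg.noise_parcel_share
    s_w = max(1.0 - s_g - s_p, 0.0)

    for design in designs:
        b = cfg.coefficients_for(design.study_id)
        for f in ("expectation", "social", "control"):
            if f not in design.factors:
                b[f] = 0.0
        if len(design.temperatures) == 1 and not design.continuous_temp:
            b["temperature"] = 0.0
        coefficients[design.study_id] = dict(b)

        n_p, n_t = design.n_participants, design.n_trials
        n = n_p * n_t
        pid = np.repeat([f"{design.study_id}_p{i + 1:03d}" for i in range(n_p)],
                        n_t)
        trial_index = np.tile(np.arange(1, n_t + 1), n_p)

        if design.continuous_temp:
            lo, hi = design.temperatures
            temp = rng.uniform(lo, hi, size=n)
        else:
            temp = rng.choice(np.asarray(design.temperatures, float), size=n)
        # cues drawn independently of stimulus intensity
        expectation = rng.choice([-1.0, 1.0], size=n)
        social = rng.choice([-1.0, 1.0], size=n)
        control = rng.uniform(0.0, 1.0, size=n)

        x = {
            "temperature": _zscore(temp),
            "expectation": _zscore(expectation),
            "social": _zscore(social),
            "control": _zscore(control),
            "habituation": _zscore(trial_index.astype(float)),
        }
        u = rng.normal(0.0, cfg.participant_sd, size=n_p)
        eps_brain = rng.normal(0.0, cfg.unique_sd, size=n)
        eps_report = rng.normal(0.0, cfg.rating_noise_sd, size=n)
        rating = (sum(b[f] * x[f] for f in factor_names)
                  + np.repeat(u, n_t) + eps_brain + eps_report)

        signal = sum(np.outer(b[f] * x[f], patterns[f]) for f in factor_names)
        signal += np.outer(cfg.unique_gain * eps_brain, patterns["pain"])
        # arousal drive: partially correlated with the decodable rating part
        decodable = sum(b[f] * x[f] for f in factor_names) + eps_brain
        sd_dec = decodable.std()
        rho = cfg.salience_rating_corr
        drive = (rho * (decodable / sd_dec if sd_dec > 0 else 0.0)
                 + math.sqrt(max(1.0 - rho**2, 0.0))
                 * rng.standard_normal(n))
        signal += np.outer(drive, patterns["salience"])
        amp = 1.0 + rng.normal(0.0, cfg.study_amp_sd)
        g = rng.standard_normal((n, q))
        shared = rng.standard_normal((n, unique_parcels.size))
        white = rng.standard_normal((n, V))
        noise = cfg.image_noise_sd * (
            math.sqrt(s_g) * (g @ modes)
            + math.sqrt(s_p) * shared[:, parcel_pos]
            + math.sqrt(s_w) * white)
        offset = cfg.study_offset_sd * rng.standard_normal(V)
        images = amp * signal + noise + offset[None, :]

        meta = pd.DataFrame({
            "participant_id": pid,
            "trial_index": trial_index,
            "rating": rating,
            "site": float(design.site),
        })
        meta["temperature"] = temp
        for f in ("expectation", "social", "control"):
            if f in design.factors:
                meta[f] = {"expectation": expectation, "social": social,
                           "control": control}[f]
        datasets.append(StudyDataset(design.study_id, parc.geometry,
                                     images, meta))

    truth = GroundTruth(cfg.scenario, parc, patterns, signal_regions,
                        coefficients)
    return datasets, truth


# ----------------------------------------------------------------------
# specificity maps


@dataclass
class TaskMapSet:
    """Per-participant task-contrast maps with task/category labels."""

    geometry: MaskGeometry
    features: np.ndarray  # (n_maps, V)
    meta: pd.DataFrame    # task, category, modality, participant_id, study_id

    @property
    def n_maps(self) -> int:
        return self.features.shape[0]


def simulate_specificity_maps(cfg: GeneratorConfig, seed: int,
                              truth: GroundTruth) -> TaskMapSet:
    """Generate per-participant mean contrast maps for 18 tasks.

    Pain-task maps contain the planted pain pattern at a modality-specific
    amplitude plus a modality component; all tasks (pain and not) share a
    salience/arousal component and carry a task-specific component, so
    non-pain tasks are superficially similar but carry no pain pattern.
    """
    rng = stage_rng(seed, "specificity")
    parc = truth.parcellation
    V = parc.geometry.n_voxels
    # the same nonspecific salience pattern that contaminated training
    salience = truth.patterns.get("salience")
    if salience is None or not np.any(salience):
        salience = _make_pattern(parc, parc.region_labels, rng)
    else:
        salience = salience / np.linalg.norm(salience)
    modality_patterns = {m: _make_pattern(parc, parc.region_labels, rng)
                         for m in ("heat", "mechanical", "visceral")}
    rows, maps = [], []
    n_p = cfg.n_specificity_participants
    for t, (task, category, modality) in enumerate(SPECIFICITY_TASKS):
        task_pattern = _make_pattern(parc, parc.region_labels, rng)
        for p in range(n_p):
            arousal = cfg.salience_amp * (
                1.0 + cfg.salience_map_jitter * rng.standard_normal())
            m = arousal * salience + cfg.task_amp * task_pattern
            if category == "pain":
                amp_m = cfg.specificity_pain_amp[modality]
                m = m + amp_m * (truth.patterns["pain"]
                                 + 0.3 * modality_patterns[modality])
            m = m + cfg.map_noise_sd * rng.standard_normal(V)
            maps.append(m)
            rows.append({
                "task": task,
                "category": category,
                "modality": modality if category == "pain" else "",
                "participant_id": f"T{t + 1:02d}_p{p + 1:02d}",
                "study_id": f"task_{task}",
            })
    return TaskMapSet(parc.geometry, np.asarray(maps), pd.DataFrame(rows))
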
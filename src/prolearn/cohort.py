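"""Synthetic cohorts with known ground truth.

Two generators provide the test bed the analysis pipeline is validated on:

* **Choice cohorts** — groups of agents simulated from a chosen model, with
  per-subject parameters drawn from group-level Gaussians in transformed
  space. The default three groups mirror the study design (124 healthy-
  control-like, 28 vmPFC-lesion-like, 21 lesion-control-like subjects) and
  their default generative means impose the qualitative orderings the real
  groups showed: controls learn faster from positive PEs for self and other
  than for no one, while the vmPFC-like group has a *lower* positive-PE
  rate for other than no one, a *higher* negative-PE rate for other than
  self, and no self advantage.
* **Lesion cohorts** — connected blob-shaped binary masks on a synthetic
  grid (no anatomical registration), accumulated around a hotspot so the
  >= 5-patient coverage criterion is met, with a behavioural score coupled
  linearly to the damaged fraction of a designated effect region:
  score = baseline + coupling * damaged_fraction + N(0, noise_sd).

Everything is reproducible bit-for-bit from the spec plus a master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitConfig, em_fit_group, transform
from .models import (
    ChoiceDataset,
    ModelSpec,
    WINNING_MODEL_ID,
    enumerate_models,
    get_model,
    simulate_agent,
)
from .selection import compare_models
from .task import build_schedule
from .vlsm import LesionMask

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "LesionCohortSpec",
    "GroundTruth",
    "default_cohort_spec",
    "generate_choice_cohort",
    "generate_lesion_cohort",
    "run_recovery",
]


# ---------------------------------------------------------------------------
# choice cohorts


@dataclass
class GroupSpec:
    """One group's generative distribution over transformed parameters."""

    name: str
    n_subjects: int
    model_id: str = WINNING_MODEL_ID
    mean_native: dict[str, float] = field(default_factory=dict)
    sd_transformed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("group sizes must be positive")
        if any(sd < 0 for sd in self.sd_transformed.values()):
            raise ValueError("generative SDs must be non-negative")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    master_seed: int = 0

    def to_json(self) -> str:
        import json
        from dataclasses import asdict

        return json.dumps(
            {"master_seed": self.master_seed, "groups": [asdict(g) for g in self.groups]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        import json

        raw = json.loads(text)
        return cls(
            groups=[GroupSpec(**g) for g in raw["groups"]],
            master_seed=raw["master_seed"],
        )


@dataclass
class GroundTruth:
    """Per-subject generative parameters (native space), kept losslessly."""

    params: dict[str, dict[str, float]]  # subject_id -> native params
    group: dict[str, str]
    model_id: dict[str, str]
    seeds: dict[str, int] = field(default_factory=dict)


_ALPHA_SD = 0.5  # generative SD of logit learning rates
_BETA_SD = 0.3  # generative SD of log temperature


def _group_defaults(name: str, means: dict[str, float]) -> GroupSpec:
    sds = {k: (_BETA_SD if k.startswith("beta") else _ALPHA_SD) for k in means}
    sizes = {"HC": 124, "vmPFC": 28, "LC": 21}
    return GroupSpec(
        name=name, n_subjects=sizes[name], mean_native=means, sd_transformed=sds
    )


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """Three study-sized groups with the observed qualitative orderings.

    Magnitudes are repository choices (group-level native means are not
    published); only the orderings between cells are meaningful.
    """
    hc = _group_defaults(
        "HC",
        {
            "alpha_self_pos": 0.55,
            "alpha_other_pos": 0.50,
            "alpha_noone_pos": 0.40,
            "alpha_self_neg": 0.35,
            "alpha_other_neg": 0.36,
            "alpha_noone_neg": 0.35,
            "beta": 3.0,
        },
    )
    vmpfc = _group_defaults(
        "vmPFC",
        {
            "alpha_self_pos": 0.45,
            "alpha_other_pos": 0.32,
            "alpha_noone_pos": 0.45,
            "alpha_self_neg": 0.32,
            "alpha_other_neg": 0.45,
            "alpha_noone_neg": 0.38,
            "beta": 3.0,
        },
    )
    lc = _group_defaults(
        "LC",
        {
            "alpha_self_pos": 0.52,
            "alpha_other_pos": 0.42,
            "alpha_noone_pos": 0.42,
            "alpha_self_neg": 0.35,
            "alpha_other_neg": 0.33,
            "alpha_noone_neg": 0.35,
            "beta": 3.0,
        },
    )
    return CohortSpec(groups=[hc, vmpfc, lc], master_seed=master_seed)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_choice_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, list[ChoiceDataset]], GroundTruth]:
    """Simulate every subject of every group on a fresh schedule.

    Per subject: draw transformed parameters from the group Gaussian,
    back-transform, build a schedule with a random recipient ordering, and
    simulate the agent. Deterministic in ``spec.master_seed``.
    """
    truth = GroundTruth(params={}, group={}, model_id={})
    datasets: dict[str, list[ChoiceDataset]] = {}
    root = np.random.SeedSequence(spec.master_seed)
    group_seeds = root.spawn(len(spec.groups))
    for gspec, gseq in zip(spec.groups, group_seeds):
        mspec = get_model(gspec.model_id)
        mu = transform(gspec.mean_native, mspec)
        sd = np.array(
            [gspec.sd_transformed.get(n, 0.0) for n in mspec.param_names]
        )
        rng = np.random.default_rng(gseq)
        subject_seqs = gseq.spawn(gspec.n_subjects)
        group_data = []
        for i, sseq in enumerate(subject_seqs):
            sid = f"{gspec.name}_{i:03d}"
            x = mu + sd * rng.standard_normal(len(mu))
            from .fitting import untransform

            params = untransform(x, mspec)
            order = int(rng.integers(0, 6))
            sim_seed = _child_seed(sseq)
            schedule = build_schedule(order, seed=sim_seed, subject_id=sid)
            ds = simulate_agent(
                params, mspec, schedule, seed=sim_seed, subject_id=sid, group=gspec.name
            )
            group_data.append(ds)
            truth.params[sid] = params
            truth.group[sid] = gspec.name
            truth.model_id[sid] = gspec.model_id
            truth.seeds[sid] = sim_seed
        datasets[gspec.name] = group_data
    return datasets, truth


def cohort_frame(datasets: dict[str, list[ChoiceDataset]]) -> pd.DataFrame:
    """All groups concatenated into one long-format trial table."""
    frames = [ds.to_frame() for group in datasets.values() for ds in group]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# lesion cohorts


@dataclass
class LesionCohortSpec:
    n_patients: int = 49
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    radius_range: tuple[int, int] = (2, 5)
    hotspot: tuple[int, int, int] | None = None  # defaults to grid centre
    hotspot_prob: float = 0.7
    hotspot_jitter_sd: float = 2.0
    effect_radius: int = 3
    coupling: float = 1.5  # score shift (in noise-SD units when noise_sd=1) at full damage
    noise_sd: float = 1.0
    baseline: float = 0.0
    laterality_axis: int = 0
    master_seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError("lesion grid must be at least 16 voxels per axis")


def _ball(center, radius, shape) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (dist2 <= radius**2).astype(np.uint8)


@dataclass
class LesionGroundTruth:
    effect_region: np.ndarray  # bool
    damaged_fraction: np.ndarray  # per patient
    coupling: float
    coverage_ok: bool


def generate_lesion_cohort(
    spec: LesionCohortSpec,
) -> tuple[list[LesionMask], np.ndarray, LesionGroundTruth]:
    """Blob lesions plus behavioural scores coupled to an effect region.

    Each patient gets one spherical blob (random radius); with probability
    ``hotspot_prob`` its centre jitters around the hotspot so that coverage
    accumulates there, otherwise it is uniform over the grid interior. The
    score couples linearly to the damaged fraction of the effect region (a
    ball of ``effect_radius`` at the hotspot).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.master_seed))
    shape = spec.grid_shape
    hotspot = (
        np.array(spec.hotspot)
        if spec.hotspot is not None
        else np.array([s // 2 for s in shape])
    )
    effect = _ball(hotspot, spec.effect_radius, shape).astype(bool)
    lo, hi = spec.radius_range
    masks: list[LesionMask] = []
    fractions = np.empty(spec.n_patients)
    n_eff = effect.sum()
    for i in range(spec.n_patients):
        radius = int(rng.integers(lo, hi + 1))
        if rng.random() < spec.hotspot_prob:
            center = hotspot + rng.normal(0, spec.hotspot_jitter_sd, size=3)
        else:
            center = np.array(
                [rng.uniform(radius, s - 1 - radius) for s in shape]
            )
        center = np.clip(np.round(center).astype(int), 0, np.array(shape) - 1)
        blob = _ball(center, radius, shape)
        masks.append(
            LesionMask(
                data=blob,
                laterality_axis=spec.laterality_axis,
                patient_id=f"P{i:03d}",
            )
        )
        fractions[i] = blob[effect].sum() / n_eff
    scores = (
        spec.baseline
        + spec.coupling * fractions
        + rng.normal(0.0, spec.noise_sd, size=spec.n_patients)
    )
    coverage = np.stack([m.data for m in masks]).sum(axis=0)
    coverage_ok = bool((coverage >= 5).any())
    if not coverage_ok:
        warnings.warn(
            "lesion cohort never reaches 5-patient coverage; VLSM inclusion "
            "mask will be empty",
            stacklevel=2,
        )
    truth = LesionGroundTruth(
        effect_region=effect,
        damaged_fraction=fractions,
        coupling=spec.coupling,
        coverage_ok=coverage_ok,
    )
    return masks, scores, truth


# ---------------------------------------------------------------------------
# recovery harness


def run_recovery(
    datasets: list[ChoiceDataset],
    truth: GroundTruth,
    spec: ModelSpec | None = None,
    fit_config: FitConfig | None = None,
    *,
    fit_all_models: bool = False,
    exceedance_seed: int = 0,
) -> dict:
    """Parameter recovery (and optionally model recovery) on one cohort.

    Fits the generating model and reports the Pearson correlation between
    generative and recovered *native* parameters; with
    ``fit_all_models=True`` also fits the whole 13-model space and reports
    the generating model's exceedance probability.
    """
    if spec is None:
        spec = get_model(truth.model_id[datasets[0].subject_id])
    fit_config = fit_config or FitConfig()
    em = em_fit_group(datasets, spec, fit_config)
    rows = []
    correlations = {}
    for name in spec.param_names:
        true_vals = np.array([truth.params[d.subject_id][name] for d in datasets])
        est_vals = np.array(
            [f.params[name] for f in em.fits]
        )
        r = float(stats.pearsonr(true_vals, est_vals).statistic)
        correlations[name] = r
        rows.append({"parameter": name, "pearson_r": r})
    report = {
        "model_id": spec.model_id,
        "correlations": correlations,
        "table": pd.DataFrame(rows),
        "em_result": em,
    }
    if fit_all_models:
        specs = enumerate_models()
        results = [
            em if s.model_id == spec.model_id else em_fit_group(datasets, s, fit_config)
            for s in specs
        ]
        comparison = compare_models(results, specs, seed=exceedance_seed)
        report["comparison"] = comparison
        report["generating_model_exceedance"] = float(
            comparison.exceedance[
                [s.model_id for s in specs].index(spec.model_id)
            ]
        )
        report["winner"] = comparison.winner()
    return report
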
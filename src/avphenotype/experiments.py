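"""Canned end-to-end experiments on synthetic cohorts.

These functions back the numbered analysis drivers and the acceptance
checks: deterministic recomputations of the published majority baselines and
balanced-accuracy identity, structural counts of the three bespoke feature
extractors, and parameter-recovery runs of the full pipeline (null
calibration, strong-effect recovery, monotonicity in effect size).

Problem sizes are chosen so a full run stays in the minutes range on one
core: recovery cohorts use 60 subjects, two low-dimensional feature sets
and the 10-fold internal-calibration fast mode; the monotonicity sweep
audits the generator's dose-response with a single logistic base classifier,
which tracks the full ensemble's ordering at a fraction of the cost.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, SkeletonParams, generate_cohort, generate_skeleton
from .conversation import conversational_features
from .evaluate import TaskSpec, majority_baseline, run_task
from .fusion import EnsembleConfig
from .movement import movement_features
from .reference import CLASSIFICATION_RESULTS, GROUP_SIZES, MB_CONTRASTS
from .speech import SpeechActivityMask
from .streams import FrameSeries, composite_lld

__all__ = [
    "recompute_majority_baselines",
    "recompute_bac_identity",
    "structural_counts",
    "null_calibration_bac",
    "strong_effect_bac",
    "effect_size_bac_curve",
]


def recompute_majority_baselines() -> dict[str, float]:
    """Majority baselines of the diagnosis contrasts from the group sizes."""
    out = {}
    for task, groups in MB_CONTRASTS.items():
        labels = []
        for g in groups:
            labels += [g] * GROUP_SIZES[g]
        out[task] = majority_baseline(labels)
    return out


def recompute_bac_identity() -> dict[str, float]:
    """BAC = (SEN+SPE)/2 recomputed from the published binary-task rows."""
    return {
        task: (row["sen"] + row["spe"]) / 2.0
        for task, row in CLASSIFICATION_RESULTS.items()
        if row["binary"]
    }


def structural_counts(seed: int = 0) -> dict[str, int]:
    """Output widths of the three bespoke extractors on synthetic inputs."""
    rng = np.random.default_rng(seed)
    n = 600
    mask = SpeechActivityMask(
        rng.integers(0, 2, n), rng.integers(0, 2, n), frame_rate=10.0
    )
    conv = conversational_features(mask, word_count_participant=100)

    skel = generate_skeleton(
        SkeletonParams(duration_s=5.0, frame_rate=30.0), np.random.default_rng(seed)
    )
    move, _ = movement_features(skel)

    lld = FrameSeries(np.arange(20.0), rng.normal(size=(20, 988)))
    comp, _ = composite_lld(lld)
    return {
        "conversational": len(conv.to_dict()),
        "movement": int(move.shape[0]),
        "lld_composite": int(comp.shape[0]),
    }


def _patient_control_bac(
    n_per_group: int,
    effect: float,
    seed: int,
    feature_sets: tuple[str, ...],
    table_dims: dict[str, int],
    ensemble: EnsembleConfig,
) -> float:
    cfg = CohortConfig(
        n_scz=n_per_group,
        n_mdd=0,
        n_hc=n_per_group,
        sessions=1,
        effect_size=effect,
        feature_sets=feature_sets,
        table_dims=table_dims,
        seed=seed,
    )
    bundle = generate_cohort(cfg)
    spec = TaskSpec(
        name="SCZ vs HC", classes=("SCZ", "HC"), feature_sets=feature_sets
    )
    report, _, _ = run_task(bundle, spec, ensemble)
    return float(report.bac)


def null_calibration_bac(seed: int = 1) -> tuple[float, tuple[float, float]]:
    """LOO BAC of the full ensemble on a zero-effect cohort (n=60).

    Returns the BAC and the 95% binomial band around chance for this n.
    """
    n = 60
    bac = _patient_control_bac(
        n_per_group=n // 2,
        effect=0.0,
        seed=seed,
        feature_sets=("LIWC",),
        table_dims={"LIWC": 30},
        ensemble=EnsembleConfig(seed=seed, calibration_cv=10),
    )
    half = 1.96 * np.sqrt(0.25 / n)
    return bac, (0.5 - half, 0.5 + half)


def strong_effect_bac(seed: int = 1) -> float:
    """Fused LOO BAC when every modality carries a d=2 effect (n=60)."""
    return _patient_control_bac(
        n_per_group=30,
        effect=2.0,
        seed=seed,
        feature_sets=("LIWC", "Diction"),
        table_dims={"LIWC": 30, "Diction": 20},
        ensemble=EnsembleConfig(seed=seed, calibration_cv=10),
    )


def effect_size_bac_curve(
    effects: tuple[float, ...] = (0.0, 1.0, 2.0), n_seeds: int = 10, seed0: int = 0
) -> dict[float, float]:
    """Mean BAC per effect size over seeds (generator dose-response audit)."""
    ens = EnsembleConfig(seed=0, calibration_cv=5, classifiers=("logreg",))
    curve = {}
    for eff in effects:
        bacs = [
            _patient_control_bac(
                n_per_group=15,
                effect=eff,
                seed=seed0 + s,
                feature_sets=("LIWC",),
                table_dims={"LIWC": 16},
                ensemble=ens,
            )
            for s in range(n_seeds)
        ]
        curve[eff] = float(np.mean(bacs))
    return curve
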
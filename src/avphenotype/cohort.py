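"""Synthetic multimodal interview cohort generator.

The clinical recordings this pipeline was designed for cannot be shared, so
every downstream stage is exercised on a synthetic cohort that reproduces the
study's structure: three diagnostic groups (schizophrenia, major depression,
healthy controls) recruited across two studies (A: longitudinal, up to three
sessions; B: cross-sectional), each subject contributing clinical ratings,
two-channel speech-activity signals, a 20-joint skeletal series, framewise
facial/acoustic descriptor streams, and eleven toolkit-style feature tables.

Generative model: one latent severity ``s ~ Normal(mu_diagnosis, 1)`` per
subject drives everything —

* clinical scores are ``group median + loading * (s - mu) + noise``, clipped
  to legal scale ranges, so group medians match the published cohort
  (e.g. NSA-Total medians about 41 / 40.5 / 29 for SCZ / MDD / HC);
* behavioral features shift by ``effect_size * s`` in standardized units;
* turn-taking parameters (speaking fraction, response latency) and skeletal
  movement amplitude vary monotonically in ``s``.

``effect_size`` is the approximate Cohen's d of patient-vs-control separation
per modality; 0 yields an exact null.  Everything is reproducible from the
config seed, with per-subject/stage seed streams so that results do not
depend on which feature sets are requested.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .conversation import CONVERSATION_FEATURE_NAMES, conversational_features
from .movement import KINECT_JOINTS, SkeletonSeries, movement_features
from .speech import SpeechActivityMask
from .streams import (
    FrameSeries,
    affectiva_style_features,
    composite_lld,
    openface_style_features,
)

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "MaskParams",
    "SkeletonParams",
    "FEATURE_SET_GROUPS",
    "ALL_FEATURE_SETS",
    "generate_cohort",
    "generate_activity_masks",
    "generate_skeleton",
    "write_cohort",
]

#: feature set -> modality group (V verbal, N nonverbal speech, F facial,
#: B body movement)
FEATURE_SET_GROUPS: dict[str, str] = {
    "LIWC": "V",
    "Diction": "V",
    "LDA": "V",
    "Doc2Vec": "V",
    "Conversational": "N",
    "OpenSMILE": "N",
    "DisVoice": "N",
    "Affectiva": "F",
    "OpenFace": "F",
    "Opsis": "F",
    "BodyMovement": "B",
}
ALL_FEATURE_SETS = tuple(FEATURE_SET_GROUPS)

def expand_feature_groups(combination: str) -> tuple[str, ...]:
    """Expand a modality-group combination string like ``"VN"`` or ``"VNFB"``
    into the corresponding feature-set names."""
    bad = set(combination.upper()) - set("VNFB")
    if bad:
        raise ValueError(f"unknown modality groups: {sorted(bad)}")
    wanted = set(combination.upper())
    return tuple(s for s, g in FEATURE_SET_GROUPS.items() if g in wanted)


#: default dimensionality of the directly drawn feature tables
_DRAWN_DIMS = {"LIWC": 77, "Diction": 42, "LDA": 100, "Doc2Vec": 100, "DisVoice": 300}

#: latent severity means per diagnosis (HC anchored at 0; unit within-group SD).
#: The patient-control separation is several SDs so that strong behavioral
#: effects can support high downstream accuracy; clinical-score medians are
#: calibrated per group and do not depend on this spacing.
LATENT_MEANS = {"HC": 0.0, "MDD": 3.3, "SCZ": 3.5}
#: reference patient severity used to convert effect sizes into per-unit-s shifts
_MU_PATIENT = 3.4

#: scale -> ({dx: group median}, loading per unit severity, clip range)
_SCALES: dict[str, tuple[dict[str, float], float, tuple[float, float]]] = {
    "nsa_total": ({"MDD": 40.5, "SCZ": 41.0, "HC": 29.0}, 7.5, (16.0, 96.0)),
    "nsa_rs": ({"MDD": 2.8, "SCZ": 2.8, "HC": 1.9}, 0.9, (0.5, 10.0)),
    "nsa_pq": ({"MDD": 3.4, "SCZ": 3.4, "HC": 1.5}, 1.0, (0.5, 10.0)),
    "nsa_ab": ({"MDD": 6.1, "SCZ": 6.4, "HC": 3.6}, 1.5, (1.0, 16.0)),
    "nsa_am": ({"MDD": 9.9, "SCZ": 9.1, "HC": 5.6}, 2.0, (1.0, 20.0)),
    "bacs_composite": ({"MDD": 0.1, "SCZ": -1.6, "HC": 0.0}, -0.8, (-5.0, 3.0)),
    "bprs_total": ({"MDD": 32.0, "SCZ": 32.0, "HC": 20.0}, 5.0, (18.0, 126.0)),
    "bprs_aff": ({"MDD": 12.4, "SCZ": 8.1, "HC": 5.5}, 1.5, (4.0, 28.0)),
    "bprs_pos": ({"MDD": 3.7, "SCZ": 7.3, "HC": 3.7}, 1.2, (3.0, 21.0)),
    "bprs_neg": ({"MDD": 7.0, "SCZ": 7.0, "HC": 4.7}, 1.2, (3.0, 21.0)),
    "bprs_res": ({"MDD": 3.9, "SCZ": 4.6, "HC": 3.1}, 0.8, (3.0, 21.0)),
    "panss_total": ({"MDD": 58.0, "SCZ": 58.0, "HC": 32.0}, 6.0, (30.0, 210.0)),
    "panss_fsns": ({"MDD": 13.0, "SCZ": 13.0, "HC": 8.0}, 2.0, (7.0, 49.0)),
}


@dataclass(frozen=True)
class CohortConfig:
    n_scz: int = 103
    n_mdd: int = 50
    n_hc: int = 75
    sessions: int = 3  # study-A subjects; study-B is cross-sectional
    #: Cohen's d of patient-vs-control separation; scalar, or mapping keyed by
    #: feature set ("LIWC"), group ("V"), or "<key>:<diagnosis>"
    effect_size: float | Mapping[str, float] = 0.8
    severity_noise_sd: float = 4.0  # NSA-Total units; other scales scaled
    frame_rate_audio: float = 100.0
    frame_rate_skeleton: float = 30.0
    facial_frame_rate: float = 15.0
    duration_s: float = 120.0
    seed: int = 0
    feature_sets: tuple[str, ...] | None = None  # None = all 11
    table_dims: Mapping[str, int] = field(default_factory=dict)
    informative_fraction: float = 0.5
    study_offset: float = 0.0  # study-B mean shift, standardized units
    overlap_prob: float = 0.1
    interject_rate_per_min: float = 1.0
    lld_dim: int = 988
    lld_window_s: float = 0.1
    envelope_noise_sd: float = 2.5  # dB, on a -30/-5 dB two-level envelope
    keep_signals: bool = True

    def __post_init__(self) -> None:
        if min(self.n_scz, self.n_mdd, self.n_hc) < 0:
            raise ValueError("group counts must be >= 0")
        if self.n_scz + self.n_mdd + self.n_hc == 0:
            raise ValueError("cohort must contain at least one subject")
        if not 1 <= self.sessions <= 3:
            raise ValueError("sessions must be in 1..3")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for fr in (self.frame_rate_audio, self.frame_rate_skeleton, self.facial_frame_rate):
            if fr <= 0:
                raise ValueError("frame rates must be positive")
        if isinstance(self.effect_size, Mapping):
            vals = list(self.effect_size.values())
        else:
            vals = [self.effect_size]
        if not np.all(np.isfinite(vals)):
            raise ValueError("effect sizes must be finite")
        if self.feature_sets is not None:
            unknown = set(self.feature_sets) - set(ALL_FEATURE_SETS)
            if unknown:
                raise ValueError(f"unknown feature sets: {sorted(unknown)}")

    @property
    def active_sets(self) -> tuple[str, ...]:
        return tuple(self.feature_sets) if self.feature_sets else ALL_FEATURE_SETS

    def effect_for(self, set_name: str, diagnosis: str) -> float:
        """Resolve the effect size for a feature set and patient group."""
        if diagnosis == "HC":
            return self.effect_for(set_name, "SCZ")  # scale only; s is near 0
        es = self.effect_size
        if not isinstance(es, Mapping):
            return float(es)
        group = FEATURE_SET_GROUPS[set_name]
        for key in (
            f"{set_name}:{diagnosis}",
            set_name,
            f"{group}:{diagnosis}",
            group,
            "all",
        ):
            if key in es:
                return float(es[key])
        return 0.0

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        if isinstance(d["effect_size"], Mapping):
            d["effect_size"] = dict(d["effect_size"])
        d["table_dims"] = dict(d["table_dims"])
        if d["feature_sets"] is not None:
            d["feature_sets"] = list(d["feature_sets"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("feature_sets") is not None:
            d["feature_sets"] = tuple(d["feature_sets"])
        return cls(**d)


@dataclass(frozen=True)
class MaskParams:
    """Parameters of the alternating-renewal turn-taking process."""

    duration_s: float
    frame_rate: float
    turn_mean_participant_s: float = 2.5
    turn_mean_interviewer_s: float = 3.0
    latency_mean_s: float = 0.5  # pause before participant takes the floor
    latency_mean_interviewer_s: float = 0.4
    log_sigma: float = 0.6  # log-normal shape for turns and pauses
    overlap_prob: float = 0.1  # chance a floor change starts in overlap
    interject_rate_per_min: float = 1.0
    speaking_fraction_participant: float = 1.0  # 0 silences the participant
    speech_level_db: float = -5.0
    silence_level_db: float = -30.0
    noise_sd_db: float = 2.5

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame rate must be positive")


@dataclass(frozen=True)
class SkeletonParams:
    duration_s: float
    frame_rate: float
    movement_energy: float = 1.0  # scales sway and jitter amplitude
    spike_rate_per_min: float = 2.0  # tracking-glitch frames
    base_depth_m: float = 2.5

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame rate must be positive")


@dataclass
class CohortBundle:
    """Everything :func:`generate_cohort` produces, keyed by record id."""

    config: CohortConfig
    clinical: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    masks: dict[str, SpeechActivityMask]
    envelopes: dict[str, np.ndarray]
    skeletons: dict[str, SkeletonSeries]
    streams: dict[str, dict[str, FrameSeries]]
    word_counts: dict[str, int]

    def records_for(self, split: str = "baseline") -> pd.DataFrame:
        """Rows of ``clinical`` for a named split.

        ``baseline``: study-A session 1 plus study-B (the pooled sample used
        for leave-one-out experiments).  ``A1``/``A2``/``A3``: study-A
        sessions.  ``B``: study-B.  ``all``: every record.
        """
        c = self.clinical
        if split == "baseline":
            return c[(c.study == "B") | (c.session == 1)]
        if split == "all":
            return c
        if split == "B":
            return c[c.study == "B"]
        if split in ("A1", "A2", "A3"):
            return c[(c.study == "A") & (c.session == int(split[1]))]
        raise ValueError(f"unknown split {split!r}")


def _rng(seed: int, *key) -> np.random.Generator:
    # stable across processes (unlike built-in str hashing)
    parts = [int(seed) % (2**31)] + [
        zlib.crc32(str(k).encode()) % (2**31) for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(parts))


def generate_activity_masks(
    params: MaskParams, rng: np.random.Generator
) -> tuple[SpeechActivityMask, np.ndarray]:
    """Simulate dyadic turn taking; return ground-truth masks and envelopes.

    The conversation alternates interviewer and participant turns with
    log-normal durations and pauses.  With probability ``overlap_prob`` a
    floor change begins before the current speaker stops (overlap); short
    interjections are injected at a Poisson rate (kept out of overlap when
    ``overlap_prob`` is 0).  The energy envelope is the two-level
    speech/silence signal plus Gaussian noise in dB.
    """
    n = int(round(params.duration_s * params.frame_rate))
    P = np.zeros(n, dtype=np.int8)
    I = np.zeros(n, dtype=np.int8)

    def _lognorm(mean: float) -> float:
        # log-normal with the requested mean and shape log_sigma
        mu = np.log(mean) - params.log_sigma**2 / 2.0
        return float(rng.lognormal(mu, params.log_sigma))

    def _paint(ch: np.ndarray, t0: float, dur: float) -> None:
        a = max(0, int(round(t0 * params.frame_rate)))
        b = min(n, int(round((t0 + dur) * params.frame_rate)))
        if b > a:
            ch[a:b] = 1

    t = 0.0
    speaker = "interviewer"
    while t < params.duration_s:
        if speaker == "participant":
            scale = params.speaking_fraction_participant
            dur = _lognorm(params.turn_mean_participant_s) * scale if scale > 0 else 0.0
            if dur > 0:
                _paint(P, t, dur)
            latency_next = params.latency_mean_interviewer_s
        else:
            dur = _lognorm(params.turn_mean_interviewer_s)
            _paint(I, t, dur)
            latency_next = params.latency_mean_s
        gap = _lognorm(latency_next)
        if params.overlap_prob > 0 and rng.random() < params.overlap_prob and dur > 0.4:
            gap = -min(float(rng.exponential(0.25)), dur / 2.0)
        t = t + dur + gap
        speaker = "participant" if speaker == "interviewer" else "interviewer"

    # interjections: brief utterances of either party
    for ch, other, active in ((P, I, params.speaking_fraction_participant > 0), (I, P, True)):
        if not active or params.interject_rate_per_min <= 0:
            continue
        k = rng.poisson(params.interject_rate_per_min * params.duration_s / 60.0)
        for _ in range(k):
            t0 = float(rng.uniform(0, params.duration_s))
            dur = float(rng.uniform(0.2, 0.6))
            a = max(0, int(round(t0 * params.frame_rate)))
            b = min(n, int(round((t0 + dur) * params.frame_rate)))
            if b <= a:
                continue
            if params.overlap_prob == 0 and other[a:b].any():
                continue  # honor the no-overlap guarantee
            ch[a:b] = 1

    mask = SpeechActivityMask(P, I, params.frame_rate)
    env = np.empty((n, 2), dtype=np.float32)
    for c, ch in enumerate((P, I)):
        level = np.where(ch == 1, params.speech_level_db, params.silence_level_db)
        env[:, c] = level + rng.normal(0.0, params.noise_sd_db, size=n)
    return mask, env


# seated base posture (metres, camera coordinates), one row per Kinect joint
_BASE_POSE = np.array(
    [
        [0.00, -0.20, 2.50],  # HipCenter
        [0.00, 0.05, 2.50],  # Spine
        [0.00, 0.30, 2.50],  # ShoulderCenter
        [0.00, 0.50, 2.50],  # Head
        [-0.18, 0.28, 2.50],  # ShoulderLeft
        [-0.25, 0.05, 2.48],  # ElbowLeft
        [-0.28, -0.15, 2.42],  # WristLeft
        [-0.29, -0.22, 2.40],  # HandLeft
        [0.18, 0.28, 2.50],  # ShoulderRight
        [0.25, 0.05, 2.48],  # ElbowRight
        [0.28, -0.15, 2.42],  # WristRight
        [0.29, -0.22, 2.40],  # HandRight
        [-0.10, -0.22, 2.50],  # HipLeft
        [-0.12, -0.45, 2.35],  # KneeLeft
        [-0.12, -0.75, 2.40],  # AnkleLeft
        [-0.12, -0.80, 2.30],  # FootLeft
        [0.10, -0.22, 2.50],  # HipRight
        [0.12, -0.45, 2.35],  # KneeRight
        [0.12, -0.75, 2.40],  # AnkleRight
        [0.12, -0.80, 2.30],  # FootRight
    ]
)


def generate_skeleton(
    params: SkeletonParams, rng: np.random.Generator
) -> SkeletonSeries:
    """Simulate a seated 20-joint skeleton with sway, jitter and spikes.

    Movement is smooth low-frequency sway plus band-limited noise, both
    scaled by ``movement_energy``; isolated spike artifacts emulate tracking
    glitches (they exercise the median filter).  Energy 0 with no spikes
    yields a perfectly static skeleton.
    """
    n = int(round(params.duration_s * params.frame_rate))
    times = np.arange(n) / params.frame_rate
    base = _BASE_POSE.copy()
    base[:, 2] += params.base_depth_m - 2.5
    coords = np.broadcast_to(base, (n, 20, 3)).copy()

    if params.movement_energy > 0:
        e = params.movement_energy
        # two slow sway components shared across joints (torso-led motion)
        for _ in range(2):
            f = rng.uniform(0.05, 0.3)
            phase = rng.uniform(0, 2 * np.pi, size=3)
            amp = e * 0.01 * rng.uniform(0.5, 1.5, size=3)
            sway = amp * np.sin(2 * np.pi * f * times[:, None] + phase)
            coords += sway[:, None, :]
        # band-limited per-joint jitter (white noise smoothed over ~0.2 s)
        from scipy.ndimage import gaussian_filter1d

        jitter = rng.normal(0, e * 0.004, size=(n, 20, 3))
        sigma = max(1.0, 0.2 * params.frame_rate)
        coords += gaussian_filter1d(jitter, sigma=sigma, axis=0)

    k = rng.poisson(params.spike_rate_per_min * params.duration_s / 60.0)
    for _ in range(int(k)):
        t = int(rng.integers(0, n))
        j = int(rng.integers(0, 20))
        c = int(rng.integers(0, 3))
        coords[t, j, c] += rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
    return SkeletonSeries(times, coords)


def _clinical_scores(diagnosis: str, s: float, config: CohortConfig, rng) -> dict:
    scores = {}
    mu = LATENT_MEANS[diagnosis]
    for scale, (medians, load, (lo, hi)) in _SCALES.items():
        noise_sd = config.severity_noise_sd * abs(load) / _SCALES["nsa_total"][1]
        val = medians[diagnosis] + load * (s - mu) + rng.normal(0.0, noise_sd)
        scores[scale] = float(np.clip(val, lo, hi))
    return scores


def _severity_shift(config: CohortConfig, set_name: str, diagnosis: str, s: float) -> float:
    """Standardized mean shift for one subject: effect_size * s / mu_patient."""
    return config.effect_for(set_name, diagnosis) * s / _MU_PATIENT


def _signature(diagnosis: str, n_inf: int) -> np.ndarray:
    """Direction of the mean shift over the informative features.

    Diagnostic groups express severity with distinct behavioral signatures
    (group-dependent effects per modality): SCZ shifts every informative
    feature positively, MDD shifts the first half positively and the second
    half negatively.  This keeps MDD-vs-SCZ separable while both remain
    separable from controls; controls (whose s is near 0) jitter along the
    SCZ direction.
    """
    u = np.ones(n_inf)
    if diagnosis == "MDD":
        u[n_inf // 2:] = -1.0
    return u


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full synthetic study bundle."""
    rows = []
    subjects = (
        [("SCZ", i) for i in range(config.n_scz)]
        + [("MDD", i) for i in range(config.n_mdd)]
        + [("HC", i) for i in range(config.n_hc)]
    )
    # study assignment mirrors the two-study structure: MDD is study-B only;
    # SCZ and HC split between A and B in the published proportions
    n_scz_a = int(round(config.n_scz * 54 / 103))
    n_hc_a = int(round(config.n_hc * 26 / 75))

    latent: dict[str, float] = {}
    meta: list[tuple[str, str, str, int]] = []  # record_id, subject, dx, session
    studies: dict[str, str] = {}
    for dx, i in subjects:
        sid = f"{dx}{i:03d}"
        if dx == "MDD":
            study = "B"
        elif dx == "SCZ":
            study = "A" if i < n_scz_a else "B"
        else:
            study = "A" if i < n_hc_a else "B"
        studies[sid] = study
        latent[sid] = float(
            LATENT_MEANS[dx] + _rng(config.seed, "latent", sid).normal()
        )
        n_sessions = config.sessions if study == "A" else 1
        for sess in range(1, n_sessions + 1):
            meta.append((f"{sid}_s{sess}", sid, dx, sess))

    active = config.active_sets
    dims = dict(_DRAWN_DIMS)
    dims.update(config.table_dims)

    masks: dict[str, SpeechActivityMask] = {}
    envelopes: dict[str, np.ndarray] = {}
    skeletons: dict[str, SkeletonSeries] = {}
    streams: dict[str, dict[str, FrameSeries]] = {k: {} for k in ("Affectiva", "OpenFace", "Opsis")}
    word_counts: dict[str, int] = {}
    table_rows: dict[str, dict[str, np.ndarray]] = {name: {} for name in active}
    table_names: dict[str, list[str]] = {}

    need_masks = "Conversational" in active
    need_skeleton = "BodyMovement" in active

    for rid, sid, dx, sess in meta:
        s = latent[sid]
        study_shift = config.study_offset if studies[sid] == "B" else 0.0
        rng_rec = _rng(config.seed, "clinical", rid)
        row = {
            "record_id": rid,
            "subject_id": sid,
            "diagnosis": dx,
            "study": studies[sid],
            "session": sess,
            "latent_severity": s,
        }
        row.update(_clinical_scores(dx, s, config, rng_rec))
        rows.append(row)

        # ---- directly drawn tables (verbal + DisVoice) -------------------
        for name in active:
            if name not in dims:
                continue
            d = dims[name]
            rng_t = _rng(config.seed, "table", name, rid)
            x = rng_t.normal(0.0, 1.0, size=d)
            n_inf = int(round(d * config.informative_fraction))
            x[:n_inf] += _severity_shift(config, name, dx, s) * _signature(dx, n_inf)
            x += study_shift
            table_rows[name][rid] = x
            table_names.setdefault(name, [f"{name}_{j}" for j in range(d)])

        # ---- conversational: masks -> 14 features ------------------------
        if need_masks:
            sev = _severity_shift(config, "Conversational", dx, s)
            mp = MaskParams(
                duration_s=config.duration_s,
                frame_rate=config.frame_rate_audio,
                turn_mean_participant_s=2.5 * float(np.exp(-0.25 * sev)),
                latency_mean_s=0.5 * float(np.exp(0.3 * sev)),
                overlap_prob=config.overlap_prob,
                interject_rate_per_min=config.interject_rate_per_min,
                noise_sd_db=config.envelope_noise_sd,
            )
            mask, env = generate_activity_masks(mp, _rng(config.seed, "mask", rid))
            rate_wps = 2.5 * float(np.exp(-0.2 * sev))
            speaking_s = float(mask.frames_participant.sum()) / mask.frame_rate
            wc = int(round(rate_wps * speaking_s))
            word_counts[rid] = wc
            feats = conversational_features(mask, wc)
            table_rows["Conversational"][rid] = feats.to_array()
            table_names.setdefault("Conversational", list(CONVERSATION_FEATURE_NAMES))
            if config.keep_signals:
                masks[rid] = mask
                envelopes[rid] = env

        # ---- body movement: skeleton -> 64 features ----------------------
        if need_skeleton:
            sev = _severity_shift(config, "BodyMovement", dx, s)
            sp = SkeletonParams(
                duration_s=config.duration_s,
                frame_rate=config.frame_rate_skeleton,
                movement_energy=float(np.exp(-0.3 * sev)),
            )
            skel = generate_skeleton(sp, _rng(config.seed, "skel", rid))
            vals, names = movement_features(skel)
            table_rows["BodyMovement"][rid] = vals
            table_names.setdefault("BodyMovement", list(names))
            if config.keep_signals:
                skeletons[rid] = skel

        # ---- facial streams -> toolkit-style summaries -------------------
        for name, descs in (
            ("Affectiva", [f"affectiva_{j}" for j in range(42)]),
            ("OpenFace", [f"AU{j:02d}_clf" for j in range(1, 18)]
             + [f"openface_{j}" for j in range(42)]),
            ("Opsis", ["Arousal", "Valence", "Intensity", "Lambda"]),
        ):
            if name not in active:
                continue
            rng_s = _rng(config.seed, "stream", name, rid)
            nf = int(round(config.duration_s * config.facial_frame_rate))
            d = len(descs)
            shift = _severity_shift(config, name, dx, s)
            base = rng_s.uniform(5.0, 30.0, size=d) if name == "Affectiva" else rng_s.normal(0, 1, size=d)
            sigma_subj = 3.0 if name == "Affectiva" else 0.5
            n_inf = int(round(d * config.informative_fraction))
            subj_off = sigma_subj * rng_s.normal(0.0, 1.0, size=d)
            subj_off[:n_inf] += sigma_subj * shift * _signature(dx, n_inf)
            subj_off += sigma_subj * study_shift
            frame_noise = rng_s.normal(0.0, sigma_subj, size=(nf, d))
            values = base + subj_off + frame_noise
            fs = FrameSeries(np.arange(nf) / config.facial_frame_rate, values, descs)
            if name == "Affectiva":
                vals, names_ = affectiva_style_features(fs, threshold=10.0)
            elif name == "OpenFace":
                vals, names_ = openface_style_features(
                    fs, au_classification=[d_ for d_ in descs if d_.endswith("_clf")]
                )
            else:
                vals, names_ = affectiva_style_features(fs, threshold=10.0)
                vals, names_ = vals[: d * 12], names_[: d * 12]  # no threshold block
            table_rows[name][rid] = vals
            table_names.setdefault(name, list(names_))
            if config.keep_signals:
                streams[name][rid] = fs

        # ---- windowed acoustic LLD stream -> 4-stat composites -----------
        if "OpenSMILE" in active:
            rng_s = _rng(config.seed, "stream", "OpenSMILE", rid)
            nw = max(1, int(round(config.duration_s / config.lld_window_s)))
            d = config.lld_dim
            shift = _severity_shift(config, "OpenSMILE", dx, s)
            n_inf = int(round(d * config.informative_fraction))
            subj_off = rng_s.normal(0.0, 1.0, size=d)
            subj_off[:n_inf] += shift * _signature(dx, n_inf)
            subj_off += study_shift
            values = subj_off + rng_s.normal(0.0, 1.0, size=(nw, d))
            fs = FrameSeries(
                np.arange(nw) * config.lld_window_s,
                values.astype(np.float32),
                [f"lld_{j}" for j in range(d)],
            )
            vals, names_ = composite_lld(fs)
            table_rows["OpenSMILE"][rid] = vals
            table_names.setdefault("OpenSMILE", list(names_))

    clinical = pd.DataFrame(rows).set_index("record_id")
    tables = {
        name: pd.DataFrame.from_dict(
            table_rows[name], orient="index", columns=table_names[name]
        ).loc[[rid for rid, *_ in meta]]
        for name in active
    }
    return CohortBundle(
        config=config,
        clinical=clinical,
        tables=tables,
        masks=masks,
        envelopes=envelopes,
        skeletons=skeletons,
        streams=streams,
        word_counts=word_counts,
    )


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write the cohort to plain-text files (CSV tables + YAML config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "config.yaml")
    bundle.clinical.to_csv(out / "clinical.csv")
    tdir = out / "features"
    tdir.mkdir(exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(tdir / f"{name}.csv")
    if bundle.masks:
        mdir = out / "masks"
        mdir.mkdir(exist_ok=True)
        for rid, mask in bundle.masks.items():
            pd.DataFrame(
                {
                    "frame": np.arange(mask.n_frames),
                    "participant": mask.frames_participant,
                    "interviewer": mask.frames_interviewer,
                }
            ).to_csv(mdir / f"{rid}.csv", index=False)
    if bundle.skeletons:
        sdir = out / "skeleton"
        sdir.mkdir(exist_ok=True)
        for rid, skel in bundle.skeletons.items():
            nf = skel.n_frames
            df = pd.DataFrame(
                {
                    "frame": np.repeat(np.arange(nf), 20),
                    "joint": np.tile(np.array(KINECT_JOINTS), nf),
                    "x": skel.coords[:, :, 0].ravel(),
                    "y": skel.coords[:, :, 1].ravel(),
                    "z": skel.coords[:, :, 2].ravel(),
                }
            )
            df.to_csv(sdir / f"{rid}.csv", index=False)
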
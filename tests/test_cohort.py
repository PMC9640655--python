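"""Synthetic cohort generator: structure, calibration, determinism."""

import numpy as np
import pytest

from avphenotype import CohortConfig, generate_cohort, write_cohort
from avphenotype.cohort import (
    ALL_FEATURE_SETS,
    FEATURE_SET_GROUPS,
    MaskParams,
    generate_activity_masks,
)


class TestConfig:
    def test_defaults_match_study_composition(self):
        cfg = CohortConfig()
        assert (cfg.n_scz, cfg.n_mdd, cfg.n_hc) == (103, 50, 75)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_scz=-1),
            dict(duration_s=0.0),
            dict(frame_rate_audio=-5.0),
            dict(sessions=4),
            dict(effect_size=float("inf")),
            dict(n_scz=0, n_mdd=0, n_hc=0),
            dict(feature_sets=("NotASet",)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_effect_size_resolution(self):
        cfg = CohortConfig(
            effect_size={"LIWC": 1.0, "V": 0.5, "N:MDD": 0.3, "all": 0.1}
        )
        assert cfg.effect_for("LIWC", "SCZ") == 1.0
        assert cfg.effect_for("Diction", "SCZ") == 0.5  # group fallback
        assert cfg.effect_for("Conversational", "MDD") == 0.3
        assert cfg.effect_for("BodyMovement", "SCZ") == 0.1

    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_scz=5, n_mdd=2, n_hc=3, feature_sets=("LIWC",), seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert CohortConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_eleven_feature_sets(self):
        assert len(ALL_FEATURE_SETS) == 11
        groups = [FEATURE_SET_GROUPS[s] for s in ALL_FEATURE_SETS]
        assert groups.count("V") == 4  # verbal
        assert groups.count("N") == 3  # nonverbal speech
        assert groups.count("F") == 3  # facial
        assert groups.count("B") == 1  # body movement


class TestGenerateCohort:
    def test_group_counts(self, tiny_bundle):
        base = tiny_bundle.records_for("baseline")
        counts = base.diagnosis.value_counts()
        assert counts["SCZ"] == 8 and counts["MDD"] == 4 and counts["HC"] == 6

    def test_one_record_per_subject_session(self, tiny_bundle):
        c = tiny_bundle.clinical
        assert c.reset_index().duplicated(["subject_id", "session"]).sum() == 0

    def test_score_ranges(self, tiny_bundle):
        c = tiny_bundle.clinical
        assert c.nsa_total.between(16, 96).all()
        assert (c.bprs_total >= 18).all()

    def test_tables_aligned_with_clinical(self, tiny_bundle):
        for name, df in tiny_bundle.tables.items():
            assert list(df.index) == list(tiny_bundle.clinical.index)
            assert np.isfinite(df.to_numpy()).all()

    def test_structural_widths(self, tiny_bundle):
        assert tiny_bundle.tables["Conversational"].shape[1] == 14
        assert tiny_bundle.tables["BodyMovement"].shape[1] == 64

    def test_mdd_assigned_to_study_b(self, tiny_bundle):
        c = tiny_bundle.clinical
        assert (c.loc[c.diagnosis == "MDD", "study"] == "B").all()
        assert (c.loc[c.study == "B", "session"] == 1).all()

    def test_determinism(self):
        cfg = CohortConfig(
            n_scz=4, n_mdd=2, n_hc=3, sessions=1, duration_s=10.0,
            feature_sets=("Conversational", "LIWC"), table_dims={"LIWC": 8}, seed=11,
        )
        b1, b2 = generate_cohort(cfg), generate_cohort(cfg)
        assert b1.clinical.equals(b2.clinical)
        for name in b1.tables:
            assert b1.tables[name].equals(b2.tables[name])
        for rid in b1.masks:
            np.testing.assert_array_equal(
                b1.masks[rid].frames_participant, b2.masks[rid].frames_participant
            )

    def test_null_effect_feature_means(self):
        """effect 0: per-feature group difference averages out across seeds."""
        ds = []
        for seed in range(10):
            cfg = CohortConfig(
                n_scz=25, n_mdd=0, n_hc=25, sessions=1, effect_size=0.0,
                feature_sets=("LIWC",), table_dims={"LIWC": 40}, seed=seed,
            )
            b = generate_cohort(cfg)
            rec = b.records_for("baseline")
            X = b.tables["LIWC"].loc[rec.index].to_numpy()
            grp = (rec.diagnosis == "SCZ").to_numpy()
            diff = X[grp].mean(axis=0) - X[~grp].mean(axis=0)
            pooled = np.sqrt((X[grp].var(axis=0) + X[~grp].var(axis=0)) / 2)
            ds.append(diff / pooled)
        mean_d = np.abs(np.mean(ds, axis=0))
        assert np.mean(mean_d < 0.2) >= 0.95

    def test_scz_nsa_median_calibrated(self):
        """Synthetic SCZ NSA-Total median lands in the reported IQR [36, 47]."""
        cfg = CohortConfig(
            n_scz=103, n_mdd=0, n_hc=10, sessions=1,
            feature_sets=("LIWC",), table_dims={"LIWC": 3}, seed=0,
        )
        b = generate_cohort(cfg)
        med = b.clinical.query("diagnosis == 'SCZ'").nsa_total.median()
        assert 36.0 <= med <= 47.0

    def test_movement_amplitude_decreases_with_severity(self):
        """Patients (high latent severity) move less than controls."""
        cfg = CohortConfig(
            n_scz=15, n_mdd=0, n_hc=15, sessions=1, duration_s=15.0,
            effect_size=2.0, feature_sets=("BodyMovement",), seed=4,
        )
        b = generate_cohort(cfg)
        rec = b.records_for("baseline")
        speed = b.tables["BodyMovement"].filter(like="linspeed_mean").mean(axis=1)
        assert speed[rec.diagnosis == "SCZ"].mean() < speed[rec.diagnosis == "HC"].mean()

    def test_speaking_decreases_with_severity(self):
        cfg = CohortConfig(
            n_scz=15, n_mdd=0, n_hc=15, sessions=1, duration_s=60.0,
            effect_size=2.0, feature_sets=("Conversational",), seed=4,
        )
        b = generate_cohort(cfg)
        rec = b.records_for("baseline")
        t = b.tables["Conversational"]
        assert (
            t.loc[rec.diagnosis == "SCZ", "speaking"].mean()
            < t.loc[rec.diagnosis == "HC", "speaking"].mean()
        )
        assert (
            t.loc[rec.diagnosis == "SCZ", "response_time"].mean()
            > t.loc[rec.diagnosis == "HC", "response_time"].mean()
        )


class TestMaskGenerator:
    def test_no_overlap_when_probability_zero(self, rng):
        params = MaskParams(
            duration_s=60.0, frame_rate=50.0, overlap_prob=0.0,
            interject_rate_per_min=4.0,
        )
        for seed in range(5):
            mask, _ = generate_activity_masks(params, np.random.default_rng(seed))
            assert not np.any(mask.frames_participant & mask.frames_interviewer)

    def test_silent_participant(self, rng):
        params = MaskParams(
            duration_s=30.0, frame_rate=50.0, speaking_fraction_participant=0.0
        )
        mask, _ = generate_activity_masks(params, rng)
        assert mask.frames_participant.sum() == 0
        assert mask.frames_interviewer.sum() > 0

    def test_bit_identical_from_seed(self):
        params = MaskParams(duration_s=20.0, frame_rate=100.0)
        m1, e1 = generate_activity_masks(params, np.random.default_rng(5))
        m2, e2 = generate_activity_masks(params, np.random.default_rng(5))
        np.testing.assert_array_equal(m1.frames_participant, m2.frames_participant)
        np.testing.assert_array_equal(m1.frames_interviewer, m2.frames_interviewer)
        np.testing.assert_array_equal(e1, e2)

    def test_envelope_levels_track_mask(self, rng):
        params = MaskParams(duration_s=30.0, frame_rate=100.0, noise_sd_db=1.0)
        mask, env = generate_activity_masks(params, rng)
        sp = env[mask.frames_participant == 1, 0].mean()
        si = env[mask.frames_participant == 0, 0].mean()
        assert sp > si + 15.0


def test_write_cohort_round_trip(tmp_path, tiny_bundle):
    import pandas as pd

    write_cohort(tiny_bundle, tmp_path / "cohort")
    clinical = pd.read_csv(tmp_path / "cohort" / "clinical.csv", index_col=0)
    assert clinical.shape[0] == tiny_bundle.clinical.shape[0]
    conv = pd.read_csv(tmp_path / "cohort" / "features" / "Conversational.csv", index_col=0)
    np.testing.assert_allclose(
        conv.to_numpy(), tiny_bundle.tables["Conversational"].to_numpy()
    )
    cfg = CohortConfig.from_yaml(tmp_path / "cohort" / "config.yaml")
    assert cfg == tiny_bundle.config
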
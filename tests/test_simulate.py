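"""Synthetic-data generator: hierarchy, determinants, outcomes, I/O."""

import numpy as np
import pandas as pd
import pytest

from codawork.composition import ilr_transform
from codawork.simulate import (
    DatasetFormatError,
    SimulationConfig,
    generate_dataset,
    matched_truncnorm,
    read_dataset,
    sample_determinants,
    sample_hierarchy,
    sample_outcomes,
    write_dataset,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"var_worker": -0.1},
            {"n_institutions": 0},
            {"p_missing_determinant": 1.5},
            {"teams_per_institution": {2: 0.5, 3: 0.4}},  # probs don't sum to 1
            {"grand_mean_composition": (0.5, 0.5, 0.0)},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, betas={"bmi": (0.01, 0.0)})
        cfg.to_yaml(tmp_path / "sim.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "sim.yaml") == cfg


class TestHierarchy:
    def test_default_counts(self):
        skel = sample_hierarchy(SimulationConfig(), _rng(1))
        assert skel["institution_id"].nunique() == 16
        assert 60 <= skel["team_id"].nunique() <= 90
        assert 140 <= len(skel) <= 230

    def test_degenerate_config_exact(self):
        cfg = SimulationConfig(n_institutions=7, teams_per_institution=1, workers_per_team=1)
        skel = sample_hierarchy(cfg, _rng(0))
        assert len(skel) == 7

    def test_nesting_is_unique(self):
        skel = sample_hierarchy(SimulationConfig(), _rng(2))
        assert skel["worker_id"].is_unique
        assert (skel.groupby("team_id")["institution_id"].nunique() == 1).all()

    def test_same_seed_same_skeleton(self):
        a = sample_hierarchy(SimulationConfig(), _rng(3))
        b = sample_hierarchy(SimulationConfig(), _rng(3))
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def big_sample():
    cfg = SimulationConfig(
        n_institutions=400, teams_per_institution=5, workers_per_team=5,
        seed=7, p_missing_determinant=0.0,
    )
    skel = sample_hierarchy(cfg, _rng(7))
    return sample_determinants(skel, cfg, _rng(7))


class TestDeterminants:

    def test_mean_age_recovered(self, big_sample):
        assert big_sample["age"].mean() == pytest.approx(36.5, abs=0.5)

    @pytest.mark.parametrize(
        "name,target,sd",
        [
            ("physical_exertion", 5.9, 1.8),
            ("bmi", 25.3, 5.3),
            ("influence", 69.8, 14.9),
            ("pain_interference", 3.5, 6.6),  # mean matched; SD not attainable
        ],
    )
    def test_continuous_means_within_3se(self, big_sample, name, target, sd):
        n = len(big_sample)
        assert abs(big_sample[name].mean() - target) < 3 * sd / np.sqrt(n) + 0.05

    def test_binary_proportions(self, big_sample):
        assert (big_sample["sex"] == "female").mean() == pytest.approx(0.843, abs=0.02)
        assert (big_sample["job_type"] == "pedagogue").mean() == pytest.approx(0.567, abs=0.02)
        insts = big_sample.drop_duplicates("institution_id")
        assert (insts["institution_type"] == "public").mean() == pytest.approx(0.625, abs=0.08)

    def test_ranges_respected(self, big_sample):
        assert big_sample["physical_exertion"].between(0, 10).all()
        assert big_sample["pain_regions"].between(0, 8).all()
        assert big_sample["pain_interference"].between(0, 28).all()

    def test_zero_sd_collapses_to_mean(self):
        cfg = SimulationConfig(determinant_overrides={"age": (40.0, 0.0, 18.0, 70.0)})
        skel = sample_hierarchy(cfg, _rng(0))
        det = sample_determinants(skel, cfg, _rng(0))
        assert (det["age"] == 40.0).all()

    def test_level_constancy(self, big_sample):
        assert (big_sample.groupby("team_id")["n_children"].nunique() == 1).all()
        assert (big_sample.groupby("institution_id")["staff_ratio"].nunique() == 1).all()


class TestMatchedTruncnorm:
    def test_exact_mean_under_heavy_truncation(self):
        from scipy import stats

        mu, sigma = matched_truncnorm(36.5, 11.7, 18.0, 70.0)
        a, b = (18.0 - mu) / sigma, (70.0 - mu) / sigma
        assert stats.truncnorm.mean(a, b, loc=mu, scale=sigma) == pytest.approx(36.5, abs=1e-6)


class TestOutcomes:
    def test_no_noise_no_effect_gives_grand_mean(self):
        cfg = SimulationConfig(
            var_worker=0.0, var_team=0.0, var_institution=0.0, betas={},
            day_noise_sd=0.0, p_missing_determinant=0.0,
        )
        w, _ = generate_dataset(cfg)
        np.testing.assert_allclose(
            w[["sb_true", "lpa_true", "mvpa_true"]].to_numpy(),
            np.tile(np.asarray(cfg.grand_mean_composition) / sum(cfg.grand_mean_composition), (len(w), 1)),
            atol=1e-12,
        )

    def test_exertion_effect_is_exact_without_noise(self):
        cfg = SimulationConfig(
            var_worker=0.0, var_team=0.0, var_institution=0.0,
            betas={"physical_exertion": (-0.03, 0.0)},
            day_noise_sd=0.0, p_missing_determinant=0.0, seed=11,
        )
        w, _ = generate_dataset(cfg)
        x = w["physical_exertion"].to_numpy()
        z1 = w["ilr1_true"].to_numpy()
        grand1 = ilr_transform(np.asarray(cfg.grand_mean_composition))[0]
        np.testing.assert_allclose(z1, grand1 - 0.03 * (x - 5.9), atol=1e-10)

    def test_worker_variance_recovered_at_n2000(self):
        cfg = SimulationConfig(
            n_institutions=100, teams_per_institution=5, workers_per_team=4,
            var_team=0.0, var_institution=0.0, betas={},
            p_missing_determinant=0.0, seed=13,
        )
        w, _ = generate_dataset(cfg)
        assert len(w) == 2000
        for coord in ("ilr1_true", "ilr2_true"):
            assert 0.070 <= w[coord].var(ddof=1) <= 0.088

    def test_day_durations_close_to_work_hours(self, default_dataset):
        _, days = default_dataset
        total = days[["sb_hours", "lpa_hours", "mvpa_hours"]].sum(axis=1)
        np.testing.assert_allclose(total, days["work_hours"], atol=1e-9)

    def test_day_count_and_hours_match_study(self, default_dataset):
        w, days = default_dataset
        per_worker = days.groupby("worker_id").size()
        assert per_worker.between(1, 5).all()
        assert per_worker.mean() == pytest.approx(3.3, abs=0.4)
        assert np.exp(np.log(days["work_hours"]).mean()) == pytest.approx(6.61, rel=0.05)

    def test_identical_seed_identical_dataset(self):
        w1, d1 = generate_dataset(SimulationConfig(seed=21))
        w2, d2 = generate_dataset(SimulationConfig(seed=21))
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_missingness_is_masked_after_outcomes(self):
        cfg = SimulationConfig(seed=5, p_missing_determinant=0.2)
        w, _ = generate_dataset(cfg)
        assert w[list(("age", "bmi", "physical_exertion"))].isna().any().any()
        # outcomes unaffected by masking: same seed with masking off
        w0, _ = generate_dataset(SimulationConfig(seed=5, p_missing_determinant=0.0))
        np.testing.assert_allclose(w["ilr1_true"], w0["ilr1_true"], atol=0)


class TestDatasetIO:
    def test_round_trip(self, tmp_path, default_dataset):
        workers, days = default_dataset
        write_dataset(workers, days, tmp_path)
        w2, d2 = read_dataset(tmp_path)
        assert len(w2) == len(workers) and len(d2) == len(days)
        np.testing.assert_allclose(
            w2["sb_true"].to_numpy(), workers["sb_true"].to_numpy(), atol=1e-12
        )
        # missing determinant cells stay missing, not zero
        assert w2["age"].isna().sum() == workers["age"].isna().sum()

    def test_duplicate_worker_id_rejected(self, tmp_path, default_dataset):
        workers, days = default_dataset
        dup = pd.concat([workers, workers.iloc[[0]]], ignore_index=True)
        write_dataset(dup, days, tmp_path)
        with pytest.raises(DatasetFormatError, match="duplicated worker id"):
            read_dataset(tmp_path)

    def test_non_numeric_cell_named(self, tmp_path, default_dataset):
        workers, days = default_dataset
        bad = workers.copy()
        bad["bmi"] = bad["bmi"].astype(object)
        bad.loc[3, "bmi"] = "heavy"
        write_dataset(bad, days, tmp_path)
        with pytest.raises(DatasetFormatError, match="bmi"):
            read_dataset(tmp_path)

    def test_unknown_day_worker_rejected(self, tmp_path, default_dataset):
        workers, days = default_dataset
        bad = days.copy()
        bad.loc[0, "worker_id"] = "GHOST"
        write_dataset(workers, bad, tmp_path)
        with pytest.raises(DatasetFormatError, match="GHOST"):
            read_dataset(tmp_path)
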
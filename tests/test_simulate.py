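"""Synthetic cohort generator: determinism, planted structure, ground truth."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import spearmanr

from tcrrep import metrics, overlap
from tcrrep.simulate import (
    ConfigError,
    SimulationConfig,
    make_naive_reference,
    simulate_cohort,
    write_cohort,
)

TINY = dict(
    n_patients=3,
    clones_per_compartment={"PBMC": 120, "ADJACENT_LUNG": 80, "TUMOR": 100},
    depth={"PBMC": 2500, "ADJACENT_LUNG": 2000, "TUMOR": 2000},
    n_viral_public_clones=10,
    n_viral_motifs=2,
    viral_reference_size=60,
)


def _dir_hashes(root: Path) -> dict:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestDeterminism:
    def test_identical_config_and_seed_give_byte_identical_files(self, tmp_path):
        h = []
        for name in ("run1", "run2"):
            cohort = simulate_cohort(SimulationConfig(**TINY), seed=77)
            write_cohort(cohort, tmp_path / name)
            h.append(_dir_hashes(tmp_path / name))
        assert h[0] == h[1]
        assert len(h[0]) >= 3 * 3 + 3  # samples + manifest/truth/reference

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_cohort(SimulationConfig(**TINY), seed=1)
        b = simulate_cohort(SimulationConfig(**TINY), seed=2)
        assert a.samples[0].cdr3_aa != b.samples[0].cdr3_aa


class TestPlantedStructure:
    def test_no_sharing_and_no_virals_give_disjoint_true_sets(self):
        config = SimulationConfig(
            **{**TINY, "n_viral_public_clones": 0, "sharing_fractions": {}}
        )
        cohort = simulate_cohort(config, seed=5)
        for pid in cohort.nsclc_patients():
            assert cohort.truth.true_jaccard(pid, "ADJACENT_LUNG", "TUMOR") == 0.0
            assert overlap.jaccard(
                cohort.sample(pid, "ADJACENT_LUNG").productive_only(),
                cohort.sample(pid, "TUMOR").productive_only(),
            ) == 0.0

    def test_configured_sharing_recovered_on_true_sets(self):
        target = 0.15
        config = SimulationConfig(
            n_patients=8,
            clones_per_compartment={"ADJACENT_LUNG": 400, "TUMOR": 400},
            depth={"ADJACENT_LUNG": 4000, "TUMOR": 4000},
            sharing_fractions={("ADJACENT_LUNG", "TUMOR"): target},
            n_viral_public_clones=0,
            survival_model={"baseline_hazard": 1e-3, "coefficients": {}},
        )
        cohort = simulate_cohort(config, seed=6)
        js = [
            cohort.truth.true_jaccard(pid, "ADJACENT_LUNG", "TUMOR")
            for pid in cohort.nsclc_patients()
        ]
        assert np.mean(js) == pytest.approx(target, abs=0.01)

    def test_uniform_latent_at_large_depth_has_near_zero_clonality(self):
        config = SimulationConfig(
            n_patients=1,
            clones_per_compartment={"TUMOR": 100},
            lognormal_sigma={"TUMOR": 0.0},
            patient_spread_jitter=(1.0, 1.0),
            depth={"TUMOR": 1_000_000},
            n_viral_public_clones=0,
            nonproductive_fraction=0.0,
            sharing_fractions={},
            survival_model={"baseline_hazard": 1e-3, "coefficients": {}},
        )
        cohort = simulate_cohort(config, seed=7)
        sample = cohort.samples[0].productive_only()
        assert metrics.clonality(sample) == pytest.approx(0.0, abs=0.01)

    def test_observed_frequencies_track_latent_at_deep_sampling(self):
        config = SimulationConfig(
            n_patients=1,
            clones_per_compartment={"TUMOR": 300},
            depth={"TUMOR": 6000},  # depth >= 10x clone count
            n_viral_public_clones=0,
            sharing_fractions={},
            survival_model={"baseline_hazard": 1e-3, "coefficients": {}},
        )
        cohort = simulate_cohort(config, seed=8)
        sample = cohort.samples[0]
        latent = cohort.truth.latent_frequencies[sample.sample_id]
        counts = sample.counts("aa")
        obs = [counts.get(c, 0) for c in latent]
        rho = spearmanr(obs, list(latent.values())).statistic
        assert rho > 0.9

    def test_every_viral_clone_embeds_its_motif_and_survives_trimming(self):
        from tcrrep.motifs import trim_cdr3

        cohort = simulate_cohort(SimulationConfig(**TINY), seed=9)
        vc = cohort.truth.viral_clones
        assert len(vc) == TINY["n_viral_public_clones"]
        for _, row in vc.iterrows():
            assert row["motif"] in row["cdr3_aa"]
            assert row["motif"] in trim_cdr3(row["cdr3_aa"])

    def test_nonproductive_rows_present_and_filtered(self):
        cohort = simulate_cohort(SimulationConfig(**TINY), seed=10)
        sample = cohort.samples[0]
        assert (~sample.productive).sum() > 0
        assert all("*" in c for c, p in zip(sample.cdr3_aa, sample.productive) if not p)
        assert all(sample.productive_only().productive)


class TestViralReference:
    def test_each_motif_backed_by_at_least_three_reference_cdr3s(self):
        cohort = simulate_cohort(SimulationConfig(**TINY), seed=11)
        ref = cohort.viral_reference
        for motif in cohort.truth.motifs:
            assert (ref["cdr3_aa"].str.contains(motif, regex=False)).sum() >= 3

    def test_decoys_never_contain_planted_motifs(self):
        cohort = simulate_cohort(SimulationConfig(**TINY), seed=12)
        planted = set(cohort.truth.viral_clones["cdr3_aa"])
        decoys = cohort.viral_reference[~cohort.viral_reference["cdr3_aa"].isin(planted)]
        for motif in cohort.truth.motifs:
            assert not decoys["cdr3_aa"].str.contains(motif, regex=False).any()

    def test_zero_planted_virals_leave_only_decoys(self):
        config = SimulationConfig(**{**TINY, "n_viral_public_clones": 0})
        cohort = simulate_cohort(config, seed=13)
        assert len(cohort.truth.viral_clones) == 0
        assert len(cohort.viral_reference) == config.viral_reference_size

    def test_naive_reference_respects_forbidden_motifs(self):
        ref = make_naive_reference(500, seed=3, forbidden_motifs=["WQRS", "HKYM"])
        assert len(ref) == 500
        assert not any("WQRS" in s or "HKYM" in s for s in ref)


class TestConfigValidation:
    def test_oversubscribed_sharing_rejected_before_writing(self, tmp_path):
        config = SimulationConfig(
            n_patients=2,
            clones_per_compartment={"PBMC": 10, "ADJACENT_LUNG": 10, "TUMOR": 10},
            sharing_fractions={
                ("PBMC", "ADJACENT_LUNG"): 0.9,
                ("PBMC", "TUMOR"): 0.9,
            },
        )
        with pytest.raises(ConfigError, match="shared clones exceed"):
            simulate_cohort(config, seed=1)
        assert list(tmp_path.iterdir()) == []

    def test_reference_must_cover_planted_virals(self):
        with pytest.raises(ConfigError, match="viral_reference_size"):
            SimulationConfig(n_viral_public_clones=50, viral_reference_size=10).validate()

    def test_unknown_survival_feature_rejected(self):
        config = SimulationConfig(
            survival_model={"baseline_hazard": 1e-3, "coefficients": {"nope": 1.0}}
        )
        with pytest.raises(ConfigError, match="survival feature"):
            config.validate()

    def test_probability_bounds_checked(self):
        config = SimulationConfig(sharing_fractions={("PBMC", "TUMOR"): 1.5})
        with pytest.raises(ConfigError, match="sharing"):
            config.validate()


class TestManifestAndSurvival:
    def test_manifest_covers_every_sample_with_clinical_columns(self, small_cohort):
        manifest = small_cohort.manifest
        assert len(manifest) == len(small_cohort.samples)
        for col in ("age", "sex", "histology", "stage", "smoking", "os_time", "os_event"):
            assert col in manifest.columns
        assert manifest.groupby(["patient_id", "compartment"]).size().max() == 1

    def test_survival_times_positive_and_truth_features_standardized(self, small_cohort):
        manifest = small_cohort.manifest
        assert (manifest["os_time"] > 0).all()
        features = small_cohort.truth.features
        for coef in small_cohort.truth.survival_coefficients:
            z = features[f"z_{coef}"]
            assert abs(z.mean()) < 1e-9
            assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
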
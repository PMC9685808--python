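import numpy as np
import pytest

from fluorosynth.errors import ContractError
from fluorosynth.fluostats import (
    DeltaSet,
    FluorParams,
    compute_deltas,
    estimate_delta_ranges,
    load_delta_ranges,
)
from fluorosynth.io_formats import DISEASED, HEALTHY, LeafLabelImage
from fluorosynth.lesionfield import SpeckleSpec
from fluorosynth.synthesis import (
    SynthesisConfig,
    build_dataset,
    plan_dataset,
    simulate_field,
    synthesize_leaf,
    synthesize_plant,
    verify_manifest,
)

DAY11 = FluorParams(107.99, 29.46, 785.74, 183.04)


class TestSimulateField:
    def test_noiseless_limit_is_constant_ratio(self, rng):
        params = FluorParams(100, 0, 700, 0)
        field = simulate_field((16, 16), params, rng)
        np.testing.assert_allclose(field.values, 1 - 100 / 700)

    def test_fixed_seed_bit_identical(self):
        a = simulate_field((32, 32), DAY11, np.random.default_rng(9))
        b = simulate_field((32, 32), DAY11, np.random.default_rng(9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_values_clipped_to_unit_interval(self, rng):
        field = simulate_field((256, 256), DAY11, rng)
        assert field.values.min() >= 0 and field.values.max() <= 1

    def test_mean_matches_monte_carlo_oracle(self):
        """The 10^6-pixel field mean agrees with a brute-force 10^7-draw
        simulation of the same ratio distribution within 3 standard errors."""
        field = simulate_field((1000, 1000), DAY11, np.random.default_rng(1))

        # independent oracle: direct vectorized draws, same redraw + clip rule
        rng = np.random.default_rng(2)
        n = 10_000_000
        a = rng.normal(DAY11.mu_f0, DAY11.sigma_f0, n)
        b = rng.normal(DAY11.mu_fm, DAY11.sigma_fm, n)
        floor = 0.05 * DAY11.mu_fm
        bad = b < floor
        while bad.any():
            b[bad] = rng.normal(DAY11.mu_fm, DAY11.sigma_fm, int(bad.sum()))
            bad = b < floor
        oracle = np.clip(1 - a / b, 0, 1)

        se = np.sqrt(field.values.var() / field.values.size + oracle.var() / n)
        assert abs(field.values.mean() - oracle.mean()) < 3 * se


class TestSynthesizeLeaf:
    def leaf(self, size=64):
        m = np.zeros((size, size), dtype=bool)
        m[8:-8, 8:-8] = True
        return m

    def test_no_lesions_gives_pure_healthy_leaf(self, rng):
        speckle = SpeckleSpec(lesion_probability=0.0)
        r = synthesize_leaf(self.leaf(), DAY11, load_delta_ranges(), speckle, rng)
        assert not r.lesion_mask.any()
        assert (r.image[self.leaf()] > 0).mean() > 0.99  # healthy Fv/Fm ~ 0.85

    def test_full_coverage_gives_pure_diseased_leaf(self, rng):
        speckle = SpeckleSpec(coverage_target=1.0, lesion_probability=1.0)
        r = synthesize_leaf(self.leaf(), DAY11, load_delta_ranges(), speckle, rng)
        np.testing.assert_array_equal(r.lesion_mask, self.leaf())

    def test_partition_covers_leaf_exactly(self, rng):
        speckle = SpeckleSpec(coverage_target=0.2, lesion_probability=1.0)
        r = synthesize_leaf(self.leaf(), DAY11, load_delta_ranges(), speckle, rng)
        leaf = self.leaf()
        assert (r.image[leaf & ~r.lesion_mask] >= 0).all()
        assert (r.image[~leaf] == 0).all()
        assert (r.lesion_mask & ~leaf).sum() == 0

    def test_lesions_darker_than_healthy_tissue(self):
        """Mean Fv/Fm over lesion pixels is below the healthy mean of the same
        leaf in >= 95% of 100 seeded runs (the core disease contrast)."""
        speckle = SpeckleSpec(coverage_target=0.1, lesion_probability=1.0)
        ranges = load_delta_ranges()
        ok = 0
        for seed in range(100):
            r = synthesize_leaf(
                self.leaf(), DAY11, ranges, speckle, np.random.default_rng(seed)
            )
            healthy_part = self.leaf() & ~r.lesion_mask
            if r.image[r.lesion_mask].mean() < r.image[healthy_part].mean():
                ok += 1
        assert ok >= 95


class TestSynthesizePlant:
    def test_single_leaf_reduces_to_synthesize_leaf(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[8:24, 8:24] = 1
        lab = LeafLabelImage(labels, source="procedural")
        sample = synthesize_plant(lab, SynthesisConfig(), seed=4)
        assert ((sample.mask > 0) == (labels > 0)).all()
        assert (sample.image[labels == 0] == 0).all()

    def test_severity_self_consistency(self, rosette_label):
        sample = synthesize_plant(rosette_label, SynthesisConfig(), seed=5)
        h, w = sample.mask.shape
        d = int((sample.mask == DISEASED).sum())
        assert sample.severity_pct == pytest.approx(100 * d / (h * w))
        p = d + int((sample.mask == HEALTHY).sum())
        assert sample.plant_size_pct == pytest.approx(100 * p / (h * w))
        assert 0 <= sample.severity_pct <= sample.plant_size_pct <= 100

    def test_fixed_seed_bit_identical(self, rosette_label):
        a = synthesize_plant(rosette_label, SynthesisConfig(), seed=6)
        b = synthesize_plant(rosette_label, SynthesisConfig(), seed=6)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_annotation_equals_replayed_lesion_overwrite(self, rosette_label):
        """The diseased class equals the union of the per-leaf lesion masks
        replayed under the later-leaf-overwrites rule — exact annotation."""
        sample = synthesize_plant(
            rosette_label, SynthesisConfig(), seed=8, keep_leaf_masks=True
        )
        disease = np.zeros(sample.mask.shape, dtype=bool)
        for entry in sample.provenance["leaf_params"]:
            leaf, lesions = entry["leaf_mask"], entry["lesion_mask"]
            disease[leaf] = lesions[leaf]
        np.testing.assert_array_equal(sample.mask == DISEASED, disease)

    def test_empty_label_rejected(self):
        lab = LeafLabelImage(np.zeros((8, 8), dtype=np.int32), source="procedural")
        with pytest.raises(ContractError):
            synthesize_plant(lab, SynthesisConfig(), seed=0)

    def test_parameter_recovery_loop(self):
        """Estimating tissue statistics on a large generated field and taking
        deltas against the generating healthy row lands inside the generating
        ranges (Monte-Carlo tolerance at >= 10^4 diseased pixels)."""
        from fluorosynth.fluostats import FluorParams as FP

        healthy = DAY11
        ranges = load_delta_ranges()
        rng = np.random.default_rng(3)
        # one big synthetic leaf: half lesions, half healthy
        from fluorosynth.synthesis import simulate_field
        from fluorosynth.fluostats import sample_diseased_params

        diseased_params = sample_diseased_params(healthy, ranges, rng)
        n = 200
        a_h = rng.normal(healthy.mu_f0, healthy.sigma_f0, (n, n))
        b_h = rng.normal(healthy.mu_fm, healthy.sigma_fm, (n, n))
        a_d = rng.normal(diseased_params.mu_f0, diseased_params.sigma_f0, (n, n))
        b_d = rng.normal(diseased_params.mu_fm, diseased_params.sigma_fm, (n, n))
        est_d = FP(a_d.mean(), a_d.std(ddof=1), b_d.mean(), b_d.std(ddof=1))
        est_h = FP(a_h.mean(), a_h.std(ddof=1), b_h.mean(), b_h.std(ddof=1))
        deltas = compute_deltas(est_h, est_d)
        lows, highs = ranges.as_arrays()
        # 3-sigma Monte-Carlo slack on each recovered delta
        slack = 3 / np.sqrt(n * n) * 2
        arr = deltas.as_array()
        assert (arr > lows - slack).all() and (arr < highs + slack).all()


class TestBuildDataset:
    def test_manifest_counts_and_uniqueness(self, tmp_path, rosette_label):
        config = SynthesisConfig()
        manifest = build_dataset([rosette_label] * 2, 3, config, 0, tmp_path)
        assert len(manifest) == 6
        assert manifest["sample_id"].is_unique
        assert manifest["seed"].nunique() == 6
        for _, rec in manifest.iterrows():
            assert (tmp_path / rec["image"]).exists()
            assert (tmp_path / rec["mask"]).exists()

    def test_rebuild_is_bit_exact(self, tmp_path, rosette_label):
        config = SynthesisConfig()
        m1 = build_dataset([rosette_label], 2, config, 7, tmp_path / "a")
        m2 = build_dataset([rosette_label], 2, config, 7, tmp_path / "b")
        assert m1["seed"].tolist() == m2["seed"].tolist()
        for _, rec in m1.iterrows():
            f1 = (tmp_path / "a" / rec["image"]).read_bytes()
            f2 = (tmp_path / "b" / rec["image"]).read_bytes()
            assert f1 == f2

    def test_verification_pass_recomputes_severity(self, tmp_path, rosette_label):
        config = SynthesisConfig()
        manifest = build_dataset([rosette_label], 2, config, 1, tmp_path)
        verified = verify_manifest(manifest, tmp_path)
        np.testing.assert_allclose(
            verified["severity_pct"], manifest["severity_pct"]
        )

    def test_plan_dataset_scales_to_published_counts(self):
        """783 source labels at 7 samples each plan out to 5481 records."""
        manifest = plan_dataset(783, 7, master_seed=0)
        assert len(manifest) == 5481
        assert manifest["sample_id"].is_unique
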
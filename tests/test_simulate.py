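"""Synthetic RRBS generator: calibration, determinism, injections."""

import numpy as np
import pytest

from m3dtest import (
    GeneratorConfig,
    GroundTruth,
    generate_base_dataset,
    inject_fixed_shift,
    inject_gaussian_bump,
    make_benchmark,
    select_alter_span,
)
from m3dtest.simulate import _bump_levels, _shift_levels


def coverage_matrix(exp, chrom="chrSim"):
    return np.stack([s.sites(chrom)[1] + s.sites(chrom)[2] for s in exp.samples])


class TestBaseDataset:
    def test_same_seed_is_bit_identical(self):
        cfg = GeneratorConfig(n_regions=40, seed=123)
        exp_a, regions_a = generate_base_dataset(cfg)
        exp_b, regions_b = generate_base_dataset(cfg)
        assert regions_a == regions_b
        for sa, sb in zip(exp_a.samples, exp_b.samples):
            assert sa.data.equals(sb.data)

    def test_different_seeds_differ(self):
        a, _ = generate_base_dataset(GeneratorConfig(n_regions=10, seed=1))
        b, _ = generate_base_dataset(GeneratorConfig(n_regions=10, seed=2))
        assert not a.samples[0].data.equals(b.samples[0].data)

    def test_coverage_calibration(self):
        exp, _ = generate_base_dataset(GeneratorConfig(n_regions=400, seed=9))
        cov = coverage_matrix(exp).ravel()
        assert cov.min() >= 1
        assert cov.mean() == pytest.approx(34.5, rel=0.05)
        assert abs(np.median(cov) - 23) <= 2

    def test_levels_in_unit_interval_and_groups_exchangeable(self):
        exp, regions = generate_base_dataset(GeneratorConfig(n_regions=60, seed=3))
        assert len(exp.group("control")) == len(exp.group("test")) == 2
        for s in exp.samples:
            level = s.data["meth"] / (s.data["meth"] + s.data["unmeth"])
            assert ((level >= 0) & (level <= 1)).all()
        assert all(r.n_sites >= 10 and r.n_sites <= 40 for r in regions)

    def test_high_precision_limit_shrinks_replicate_disagreement(self):
        def disagreement(kappa):
            cfg = GeneratorConfig(n_regions=60, seed=21, replicate_precision=kappa)
            exp, _ = generate_base_dataset(cfg)
            a, b = exp.group("control")
            la = a.sites("chrSim")[1] / np.maximum(1, a.sites("chrSim")[1] + a.sites("chrSim")[2])
            lb = b.sites("chrSim")[1] / np.maximum(1, b.sites("chrSim")[1] + b.sites("chrSim")[2])
            return np.mean(np.abs(la - lb))

        assert disagreement(1e7) < disagreement(5.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(coverage_mean=-1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(mean_spacing=1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(low_beta=(0.0, 1.0))


class TestShiftRule:
    def test_hyper_at_full_strength_reaches_one(self):
        l_new, direction = _shift_levels(np.array([0.2, 0.2]), alpha=1.0)
        assert direction == "hyper"
        np.testing.assert_allclose(l_new, 1.0)

    def test_hyper_partial_strength(self):
        l_new, direction = _shift_levels(np.array([0.2]), alpha=0.4)
        assert direction == "hyper"
        assert l_new[0] == pytest.approx(0.52)

    def test_hypo_partial_strength(self):
        l_new, direction = _shift_levels(np.array([0.8]), alpha=0.6)
        assert direction == "hypo"
        assert l_new[0] == pytest.approx(0.32)

    def test_alpha_zero_is_identity(self):
        l = np.array([0.3, 0.7])
        l_new, _ = _shift_levels(l, alpha=0.0)
        np.testing.assert_allclose(l_new, l)


class TestBumpRule:
    def test_zero_height_is_identity(self):
        l = np.array([0.2, 0.9])
        out = _bump_levels(l, np.array([0.0, 50.0]), center=10.0, width_bp=30.0, height=0.0)
        np.testing.assert_allclose(out, l)

    def test_site_at_center_gets_full_height(self):
        out = _bump_levels(np.array([0.1]), np.array([100.0]), center=100.0, width_bp=50.0, height=0.5)
        assert out[0] == pytest.approx(0.6)

    def test_clipping_at_one(self):
        out = _bump_levels(np.array([0.9]), np.array([100.0]), center=100.0, width_bp=50.0, height=0.5)
        assert out[0] == 1.0


class TestInjections:
    @pytest.fixture()
    def base(self):
        cfg = GeneratorConfig(n_regions=12, seed=42)
        exp, regions = generate_base_dataset(cfg)
        return exp, regions

    def test_coverage_never_modified(self, base):
        exp, regions = base
        group = exp.group("test")
        rng = np.random.default_rng(0)
        region = regions[0]
        span, whole = select_alter_span(region, group, rng)
        altered, entry = inject_fixed_shift(group, region, span, alpha=1.0, rng=rng, whole_region=whole)
        for before, after in zip(group, altered):
            np.testing.assert_array_equal(
                before.data["meth"] + before.data["unmeth"],
                after.data["meth"] + after.data["unmeth"],
            )

    def test_full_hyper_shift_saturates_span(self, base):
        exp, regions = base
        group = exp.group("test")
        rng = np.random.default_rng(1)
        for region in regions:
            span, whole = select_alter_span(region, group, rng)
            altered, entry = inject_fixed_shift(group, region, span, 1.0, rng, whole_region=whole)
            if entry.direction != "hyper":
                continue
            # Binomial(n, 1) is deterministic: every span read methylated
            for s in altered:
                m, u = s.counts_at(region.chrom, np.asarray(span))
                assert (u == 0).all() and (m >= 1).all()
            return
        pytest.fail("no hyper-direction region found")

    def test_span_constraints_when_region_allows(self, base):
        exp, regions = base
        group = exp.group("test")
        rng = np.random.default_rng(3)
        for region in regions:
            span, whole = select_alter_span(region, group, rng)
            assert set(span) <= set(region.site_positions)
            if not whole:
                assert span[-1] - span[0] + 1 >= 100
                pos = np.asarray(span)
                cov = sum(
                    (s.counts_at(region.chrom, pos)[0] + s.counts_at(region.chrom, pos)[1]).sum()
                    for s in group
                )
                assert cov >= 100

    def test_span_deterministic_given_rng_state(self, base):
        exp, regions = base
        group = exp.group("test")
        s1, _ = select_alter_span(regions[2], group, np.random.default_rng(77))
        s2, _ = select_alter_span(regions[2], group, np.random.default_rng(77))
        assert s1 == s2

    def test_bump_injection_preserves_coverage(self, base):
        exp, regions = base
        group = exp.group("test")
        rng = np.random.default_rng(5)
        region = regions[1]
        altered, entry = inject_gaussian_bump(group, region, center=region.start + 50,
                                              width_bp=80.0, height=0.6, rng=rng)
        assert entry.mechanism == "bump" and entry.direction == "hyper"
        for before, after in zip(group, altered):
            np.testing.assert_array_equal(
                before.data["meth"] + before.data["unmeth"],
                after.data["meth"] + after.data["unmeth"],
            )

    def test_alpha_out_of_range_rejected(self, base):
        exp, regions = base
        group = exp.group("test")
        with pytest.raises(ValueError):
            inject_fixed_shift(group, regions[0], regions[0].site_positions, 1.5,
                               np.random.default_rng(0))


class TestMakeBenchmark:
    def test_counts_and_truth_bookkeeping(self):
        cfg = GeneratorConfig(n_regions=50, seed=8)
        exp, regions, truth = make_benchmark(cfg, alpha=1.0, n_altered=12)
        assert len(regions) == 50
        assert len(truth.altered_region_ids) == 12
        assert truth.altered_region_ids <= {r.region_id for r in regions}
        for e in truth.entries.values():
            region = regions[e.region_id]
            assert set(e.affected_positions) <= set(region.site_positions)

    def test_control_group_untouched_and_coverage_preserved(self):
        cfg = GeneratorConfig(n_regions=30, seed=13)
        base_exp, _ = generate_base_dataset(cfg)
        exp, _, _ = make_benchmark(cfg, alpha=1.0, n_altered=10)
        for b, a in zip(base_exp.group("control"), exp.group("control")):
            assert b.data.equals(a.data)
        np.testing.assert_array_equal(coverage_matrix(base_exp), coverage_matrix(exp))

    def test_two_seeds_give_different_alteration_sets(self):
        _, _, t1 = make_benchmark(GeneratorConfig(n_regions=60, seed=1), n_altered=15)
        _, _, t2 = make_benchmark(GeneratorConfig(n_regions=60, seed=2), n_altered=15)
        assert t1.altered_region_ids != t2.altered_region_ids

    def test_truth_roundtrip_through_frame(self):
        _, _, truth = make_benchmark(GeneratorConfig(n_regions=40, seed=4), n_altered=10)
        back = GroundTruth.from_frame(truth.to_frame())
        assert back.entries == truth.entries

    def test_n_altered_bounded(self):
        with pytest.raises(ValueError):
            make_benchmark(GeneratorConfig(n_regions=5, seed=0), n_altered=6)
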
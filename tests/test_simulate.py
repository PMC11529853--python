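import numpy as np
import pytest

from amplicycle.coverage import CoverageProfile
from amplicycle.simulate import (
    GroundTruth,
    NoiseSpec,
    Template,
    TemplateSpec,
    build_coverage,
    detectable_templates,
    emit_fixture,
    mix_fixtures,
    ring_junctions,
    simulate_template,
    simulate_truth,
)
from amplicycle.sv import parse_sv_vcf
from amplicycle.topology import TOPOLOGY_NAMES, classify_ring


class TestTemplates:
    def test_no_events_gives_single_fragment_simple_circle(self):
        spec = TemplateSpec(del_ratio=0, inv_ratio=0, dup_ratio=0,
                            foldback_ratio=0, seed=1)
        ring = simulate_template(spec)
        assert len(ring) == 1 and ring[0][3] == "+"
        assert classify_ring(ring).name == "SimpleCircularization"

    def test_same_seed_reproduces_ring_different_seeds_differ(self):
        spec = TemplateSpec(seed=11)
        assert simulate_template(spec) == simulate_template(spec)
        assert simulate_template(spec) != simulate_template(TemplateSpec(seed=12))

    def test_mixed_events_produce_expected_shapes(self):
        """One DEL + one DUP + one INV leaves a gap, a repeated segment and
        an inverted segment on the ring."""
        spec = TemplateSpec(target_topology="Duplications", del_ratio=1.0,
                            inv_ratio=1.0, dup_ratio=1.0, seed=5)
        ring = simulate_template(spec)
        intervals = [(s, e) for _, s, e, _ in ring]
        assert len(intervals) > len(set(intervals))  # repeated segment
        assert any(o == "-" for *_, o in ring)  # inverted segment
        starts = sorted(e for _, e, *_ in ring)
        assert classify_ring(ring).name == "Duplications"

    @pytest.mark.parametrize("topology", TOPOLOGY_NAMES)
    def test_target_topology_closure(self, topology):
        """classify(simulate(target=T)) == T over 50 seeded draws."""
        for seed in range(50):
            ring = simulate_template(TemplateSpec(target_topology=topology, seed=seed))
            assert classify_ring(ring).name == topology


class TestEmission:
    def test_single_circle_bookkeeping(self, tmp_path):
        """Simple circle at 40 copies over 5x background: one DUP-type
        record with support 40; coverage 45 inside, 5 outside."""
        ring = [("chr1", 1_000_000, 1_250_000, "+")]
        truth = GroundTruth([Template("T0", ring, 40.0, "SimpleCircularization")])
        fx = emit_fixture(truth, NoiseSpec(), tmp_path, np.random.default_rng(0))
        (rec,) = parse_sv_vcf(fx.vcf)
        assert rec.svtype == "DUP"
        assert (rec.pos1, rec.pos2) == (1_000_000, 1_250_000)
        assert rec.support == 40
        assert fx.profile.value_at("chr1", 1_100_000) == 45.0
        assert fx.profile.value_at("chr1", 500_000) == 5.0

    def test_zero_templates_yield_empty_vcf_and_flat_track(self, tmp_path):
        truth = GroundTruth([])
        fx = emit_fixture(truth, NoiseSpec(), tmp_path, np.random.default_rng(0))
        assert parse_sv_vcf(fx.vcf) == []
        s, e, v = fx.profile.data["chr1"]
        assert list(v) == [5.0]

    def test_junction_false_negative_rate_drops_records(self, tmp_path):
        truth = simulate_truth(1, seed=3, target_topology="MixedSVs")
        full = emit_fixture(truth, NoiseSpec(), tmp_path / "a", np.random.default_rng(1))
        dropped = emit_fixture(
            truth, NoiseSpec(fn_rate=1.0), tmp_path / "b", np.random.default_rng(1)
        )
        assert len(parse_sv_vcf(full.vcf)) > 0
        assert parse_sv_vcf(dropped.vcf) == []

    def test_breakend_jitter_stays_within_bound(self, tmp_path):
        truth = simulate_truth(1, seed=4, target_topology="SimpleSVs")
        exact = emit_fixture(truth, NoiseSpec(), tmp_path / "a", np.random.default_rng(1))
        jit = emit_fixture(
            truth, NoiseSpec(bp_jitter=10), tmp_path / "b", np.random.default_rng(1)
        )
        exact_pos = sorted(
            (r.chrom1, r.pos1, r.chrom2, r.pos2) for r in parse_sv_vcf(exact.vcf)
        )
        jit_pos = sorted(
            (r.chrom1, r.pos1, r.chrom2, r.pos2) for r in parse_sv_vcf(jit.vcf)
        )
        for a, b in zip(exact_pos, jit_pos):
            assert a[0] == b[0] and a[2] == b[2]
            assert abs(a[1] - b[1]) <= 10 and abs(a[3] - b[3]) <= 10


def test_ring_junctions_skip_colinear_adjacency():
    ring = [
        ("chr1", 0, 1000, "+"),
        ("chr1", 1000, 2000, "+"),  # adjacency: no junction
        ("chr1", 5000, 6000, "+"),  # deletion-type jump
    ]
    juncs = ring_junctions(ring)
    assert len(juncs) == 2  # DEL jump + circularization
    assert (("chr1", 2000, "h"), ("chr1", 5000, "t")) in juncs


class TestMixtures:
    def test_identity_and_ratio_validation(self):
        truth = simulate_truth(1, seed=0)
        same = mix_fixtures([truth], [1.0])
        assert [t.proportion for t in same.templates] == [
            t.proportion for t in truth.templates
        ]
        with pytest.raises(ValueError):
            mix_fixtures([truth], [1.0, 0.5])
        with pytest.raises(ValueError):
            mix_fixtures([truth], [0.0])

    def test_half_half_mix_halves_each_coverage(self):
        t1 = simulate_truth(1, seed=1)
        t2 = simulate_truth(1, seed=2)
        mixed = mix_fixtures([t1, t2], [0.5, 0.5])
        assert mixed.templates[0].proportion == t1.templates[0].proportion / 2
        assert mixed.templates[1].proportion == t2.templates[0].proportion / 2
        assert mixed.background_cov == pytest.approx(5.0)

    def test_coverage_mass_is_conserved_linearly(self):
        t1 = simulate_truth(1, seed=1)
        t2 = simulate_truth(1, seed=2)
        noise = NoiseSpec()
        m1 = build_coverage(t1, noise).total_mass()
        m2 = build_coverage(t2, noise).total_mass()
        bg = build_coverage(GroundTruth([]), noise).total_mass()
        mixed = build_coverage(mix_fixtures([t1, t2], [0.25, 0.75]), noise).total_mass()
        assert mixed == pytest.approx(0.25 * (m1 - bg) + 0.75 * (m2 - bg) + bg, rel=1e-9)

    def test_full_strength_union_mix(self):
        """The 100% + 100% design simply unions the two samples."""
        t1 = simulate_truth(1, seed=1)
        t2 = simulate_truth(1, seed=2)
        mixed = mix_fixtures([t1, t2], [1.0, 1.0])
        assert len(mixed.templates) == 2
        assert mixed.background_cov == 10.0


def test_detectable_templates_tracks_dilution():
    ring = [("chr1", 1_000_000, 1_250_000, "+")]
    truth = GroundTruth([Template("T0", ring, 80.0, "SimpleCircularization")])
    assert detectable_templates(truth) == [True]
    faint = mix_fixtures([truth], [0.05])  # proportion 4, background 0.25
    assert detectable_templates(faint) == [False]
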
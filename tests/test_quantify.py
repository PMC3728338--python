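"""ppm arithmetic, confounder triage, pooling and coverage profiles."""

import numpy as np
import pytest

from cfplant import (
    AlignmentHit,
    AlignmentPolicy,
    CoverageProfile,
    ReferencePanel,
    SequencingRead,
    StudyDesign,
    align_read,
    build_index,
    compute_ppm,
    coverage_ratio,
    cross_screen,
    generate_genome,
    implant_conserved_region,
    pileup,
    pool_fractions,
    simulate_study,
    smooth_coverage,
    subtract_host,
    whole_ppm,
)
from cfplant.quantify import SampleConcentration


class TestPpm:
    # printed (k, N, ppm) values from published cfDNA screening tables
    @pytest.mark.parametrize(
        "k,N,expected",
        [
            (23319, 163948523, 142.234),
            (0, 10**6, 0.000),
            (1634, 3284956, 497.419),
            (622, 435118157, 1.429),
            (1110, 1578181738, 0.703),
            (3, 672693854, 0.004),
        ],
    )
    def test_half_up_display(self, k, N, expected):
        assert compute_ppm(k, N) == expected

    def test_truncate_mode(self):
        # 23649/478515084 = 49.42164: truncation gives 49.421, half-up 49.422
        assert compute_ppm(23649, 478515084, mode="truncate") == 49.421
        assert compute_ppm(23649, 478515084) == 49.422

    def test_whole_ppm_floor(self):
        assert whole_ppm(23649, 478515084) == 49
        assert whole_ppm(1634, 3284956) == 497

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_ppm(1, 0)
        with pytest.raises(ValueError):
            compute_ppm(5, 4)

    def test_ppm_at_least_detection_limit_when_detected(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            N = int(rng.integers(1_000, 10**7))
            k = int(rng.integers(1, 100))
            s = SampleConcentration("s", N, min(k, N))
            assert s.ppm_exact >= s.detection_limit_exact


class TestPoolFractions:
    def test_ibd_fraction_pooling(self):
        rows = [
            SampleConcentration("IBD", 163948523, 23319, fraction=">10 kb"),
            SampleConcentration("IBD", 148952652, 237, fraction="200 bp-10 kb"),
            SampleConcentration("IBD", 165613909, 93, fraction="~200 bp"),
        ]
        pooled = pool_fractions(rows)
        assert pooled.total_reads == 478_515_084
        assert pooled.foreign_reads == 23_649
        assert compute_ppm(
            pooled.foreign_reads, pooled.total_reads, mode="truncate"
        ) == 49.421

    def test_single_row_identity(self):
        row = SampleConcentration("x", 1000, 3, fraction="f1")
        pooled = pool_fractions([row])
        assert (pooled.total_reads, pooled.foreign_reads) == (1000, 3)
        assert pooled.ppm == row.ppm

    def test_duplicate_fraction_rejected(self):
        rows = [
            SampleConcentration("x", 1000, 3, fraction="f1"),
            SampleConcentration("x", 2000, 1, fraction="f1"),
        ]
        with pytest.raises(ValueError):
            pool_fractions(rows)

    def test_mixed_samples_rejected(self):
        rows = [
            SampleConcentration("x", 1000, 3, fraction="f1"),
            SampleConcentration("y", 2000, 1, fraction="f2"),
        ]
        with pytest.raises(ValueError):
            pool_fractions(rows)


@pytest.fixture(scope="module")
def homology_setup():
    foreign = generate_genome(8_000, 0.36, 61, ref_id="plastA", group="foreign")
    bact = generate_genome(
        12_000, 0.5, 62, ref_id="bactA", group="confounder_bacteria"
    )
    mam = generate_genome(
        12_000, 0.42, 63, ref_id="mamA", group="confounder_mammal"
    )
    bact = implant_conserved_region(foreign, bact, 2_000, 0.0, seed=64)
    conf = ReferencePanel("conf", [bact, mam])
    index = build_index(conf, 28)
    return foreign, bact, mam, index


class TestCrossScreen:
    def test_read_from_conserved_region_is_also_bacteria(self, homology_setup):
        foreign, bact, _, index = homology_setup
        imp = bact.implants[0]
        src = imp["source_start"]
        read = SequencingRead("r1", foreign.sequence[src + 10 : src + 60])
        (cls,) = cross_screen([read], index)
        assert cls.label == "also_bacteria"

    def test_read_outside_conserved_region_is_plants_only(self, homology_setup):
        foreign, bact, _, index = homology_setup
        imp = bact.implants[0]
        pos = (imp["source_start"] + imp["length"] + 100) % (len(foreign) - 60)
        # ensure the window is fully outside the donated region
        while imp["source_start"] - 60 < pos < imp["source_start"] + imp["length"]:
            pos = (pos + 500) % (len(foreign) - 60)
        read = SequencingRead("r2", foreign.sequence[pos : pos + 50])
        (cls,) = cross_screen([read], index)
        assert cls.label == "plants_only"

    def test_mammal_homolog_label_and_bacteria_precedence(self):
        foreign = generate_genome(8_000, 0.36, 71, ref_id="p", group="foreign")
        bact = generate_genome(8_000, 0.5, 72, ref_id="b",
                               group="confounder_bacteria")
        mam = generate_genome(8_000, 0.42, 73, ref_id="m",
                              group="confounder_mammal")
        # same foreign stretch implanted into both confounders
        region = foreign.sequence[1000:1100]
        mam.sequence = mam.sequence[:500] + region + mam.sequence[600:]
        read = SequencingRead("r", region[10:60])
        index_m = build_index(ReferencePanel("c", [mam]), 28)
        (cls_m,) = cross_screen([read], index_m)
        assert cls_m.label == "also_mammalia"
        bact.sequence = bact.sequence[:2000] + region + bact.sequence[2100:]
        index_bm = build_index(ReferencePanel("c", [bact, mam]), 28)
        (cls_bm,) = cross_screen([read], index_bm)
        assert cls_bm.label == "also_bacteria"

    def test_no_conserved_regions_no_confounder_labels(self, clean_panels):
        host, foreign, conf = clean_panels
        design = StudyDesign(
            n_samples=2, depth_range=(300, 300), fixed_concentration_ppm=3e5,
            error_rate=0.0, seed=75,
        )
        reads, _ = simulate_study(design, host, foreign)
        spiked = [r for r in reads if r.origin_group == "foreign"]
        classes = cross_screen(spiked, build_index(conf))
        assert {c.label for c in classes} == {"plants_only"}


class TestRecoveredCounts:
    def test_exact_recovery_without_errors(self, clean_panels):
        host, foreign, _ = clean_panels
        design = StudyDesign(
            n_samples=3, depth_range=(500, 500), fixed_concentration_ppm=1e5,
            error_rate=0.0, seed=80,
        )
        reads, truth = simulate_study(design, host, foreign)
        _, survivors = subtract_host(reads, build_index(host))
        fidx = build_index(foreign)
        stringent = AlignmentPolicy.stringent()
        per_sample: dict[str, int] = {}
        for r in survivors:
            if align_read(r, fidx, stringent, first_hit_only=True):
                per_sample[r.sample] = per_sample.get(r.sample, 0) + 1
        for _, row in truth.iterrows():
            assert per_sample.get(row.sample_id, 0) == row.true_foreign_read_count

    def test_recovery_bounded_by_truth_with_errors(self, clean_panels):
        host, foreign, _ = clean_panels
        design = StudyDesign(
            n_samples=3, depth_range=(500, 500), fixed_concentration_ppm=1e5,
            error_rate=0.02, seed=81,
        )
        reads, truth = simulate_study(design, host, foreign)
        _, survivors = subtract_host(reads, build_index(host))
        fidx = build_index(foreign)
        stringent = AlignmentPolicy.stringent()
        k = sum(
            1 for r in survivors
            if align_read(r, fidx, stringent, first_hit_only=True)
        )
        assert k <= truth["true_foreign_read_count"].sum()


@pytest.fixture(scope="module")
def cov_ref():
    r = generate_genome(1_000, 0.5, 90, ref_id="cov")
    r.sequence = r.sequence[:100]  # shrink after the length check
    return r


class TestPileup:
    def test_no_hits(self, cov_ref):
        profile = pileup([], cov_ref, 50)
        assert profile.positions_covered == 0
        assert profile.mean_coverage == 0.0

    def test_two_overlapping_hits(self, cov_ref):
        hits = [
            AlignmentHit("a", "cov", 0, "+", 0, 0),
            AlignmentHit("b", "cov", 25, "+", 0, 0),
        ]
        profile = pileup(hits, cov_ref, 50)
        assert profile.positions_covered == 75
        assert profile.mean_coverage == 1.0
        assert profile.depth[30] == 2

    def test_matches_interval_oracle(self, oracle_pileup):
        ref = generate_genome(2_000, 0.5, 91, ref_id="cov2")
        rng = np.random.default_rng(92)
        hits = [
            AlignmentHit(f"r{i}", "cov2", int(s), "+", 0, 0)
            for i, s in enumerate(rng.integers(0, 2_000 - 50 + 1, size=400))
        ]
        profile = pileup(hits, ref, 50)
        assert np.array_equal(profile.depth, oracle_pileup(hits, 2_000, 50))
        # total depth equals hits x read length
        assert profile.depth.sum() == 400 * 50

    def test_overrun_rejected(self, cov_ref):
        with pytest.raises(ValueError):
            pileup([AlignmentHit("a", "cov", 60, "+", 0, 0)], cov_ref, 50)
        with pytest.raises(ValueError):
            pileup([AlignmentHit("a", "other", 0, "+", 0, 0)], cov_ref, 50)


class TestSmoothing:
    def test_window_one_is_identity(self):
        depth = np.array([0.0, 1, 5, 2, 0])
        profile = CoverageProfile("x", depth)
        assert np.array_equal(smooth_coverage(profile, 1), depth)

    def test_constant_track_unchanged(self):
        profile = CoverageProfile("x", np.full(500, 7))
        assert np.allclose(smooth_coverage(profile, 101), 7.0)

    def test_impulse_becomes_plateau(self):
        depth = np.zeros(3001)
        depth[1500] = 1.0
        sm = smooth_coverage(CoverageProfile("x", depth), 1001)
        assert np.allclose(sm[1000:2001], 1 / 1001)
        assert np.allclose(sm[:1000], 0.0)
        assert np.allclose(sm[2001:], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_coverage(CoverageProfile("x", np.zeros(10)), 10)


class TestCoverageRatio:
    def test_published_style_ratio(self):
        assert coverage_ratio(6.3, 4.9) == pytest.approx(6.3 / 4.9)
        assert coverage_ratio(5.0, 5.0) == 1.0

    def test_zero_host_coverage_rejected(self):
        with pytest.raises(ValueError):
            coverage_ratio(1.0, 0.0)
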
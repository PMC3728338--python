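"""Seed-index aligner: exactness, policy semantics and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfplant import (
    AlignmentPolicy,
    ReferencePanel,
    SequencingRead,
    align_read,
    build_index,
    generate_genome,
    revcomp,
    subtract_host,
)


def mutate(seq: str, positions, rng=None) -> str:
    """Substitute each given position with a different base."""
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


@pytest.fixture(scope="module")
def genome_panel():
    refs = [
        generate_genome(10_000, 0.45, seed=31, ref_id="r1"),
        generate_genome(10_000, 0.45, seed=32, ref_id="r2"),
    ]
    return ReferencePanel("panel", refs)


@pytest.fixture(scope="module")
def index28(genome_panel):
    return build_index(genome_panel, 28)


class TestSeedIndex:
    def test_kmer_positions_small(self):
        ref = generate_genome(1_000, 0.5, seed=1, ref_id="tiny")
        ref.sequence = "ACGTACGT" + ref.sequence[8:]
        idx = build_index(ReferencePanel("p", [ref]), 4)
        fwd = [e for e in idx.get("ACGT") if e[2] == "+" and e[1] < 8]
        assert [p for _, p, _ in fwd] == [0, 4]

    def test_palindromic_kmer_indexed_on_both_strands(self):
        ref = generate_genome(1_000, 0.5, seed=2, ref_id="p")
        # ACGT is its own reverse complement
        ref.sequence = "ACGT" + "A" * 24 + ref.sequence[28:]
        idx = build_index(ReferencePanel("p", [ref]), 4)
        entries = [e for e in idx.get("ACGT") if e[1] == 0]
        assert {s for _, _, s in entries} == {"+", "-"}

    def test_every_position_recoverable(self, genome_panel, index28):
        ref = genome_panel.references[0]
        rng = np.random.default_rng(3)
        for p in rng.integers(0, len(ref) - 28, size=20):
            kmer = ref.sequence[p : p + 28]
            assert (ref.id, int(p), "+") in index28.get(kmer)

    def test_short_reference_skipped_with_warning(self, caplog):
        ref = generate_genome(1_000, 0.5, seed=4, ref_id="short")
        idx = build_index(ReferencePanel("p", [ref]), 2_000)
        assert idx.skipped_references == ["short"]


class TestAlignRead:
    def test_exact_copy_single_hit(self, genome_panel, index28):
        ref = genome_panel.references[0]
        read = ref.sequence[100:150]
        (hit,) = align_read(read, index28, AlignmentPolicy.stringent())
        assert (hit.ref_id, hit.start, hit.strand) == (ref.id, 100, "+")
        assert hit.mismatches_total == 0

    def test_seed_mismatch_stringent_vs_permissive(self, genome_panel, index28):
        # one substitution inside the 28-nt seed: rejected by the exact-seed
        # policy, accepted permissively with 1 total mismatch
        ref = genome_panel.references[0]
        read = mutate(ref.sequence[100:150], [10])
        assert align_read(read, index28, AlignmentPolicy.stringent()) == []
        hits = align_read(read, index28, AlignmentPolicy.permissive())
        assert any(
            h.start == 100 and h.ref_id == ref.id and h.mismatches_total == 1
            for h in hits
        )

    def test_tail_mismatches_allowed_stringently(self, genome_panel, index28):
        ref = genome_panel.references[0]
        read = mutate(ref.sequence[200:250], [30, 45])
        hits = align_read(read, index28, AlignmentPolicy.stringent())
        assert any(h.start == 200 and h.mismatches_total == 2 for h in hits)
        read3 = mutate(ref.sequence[200:250], [30, 40, 45])
        assert not any(
            h.start == 200
            for h in align_read(read3, index28, AlignmentPolicy.stringent())
        )

    def test_minus_strand_hit(self, genome_panel, index28):
        ref = genome_panel.references[1]
        read = revcomp(ref.sequence[300:350])
        hits = align_read(read, index28, AlignmentPolicy.stringent())
        assert any(
            h.ref_id == ref.id and h.start == 300 and h.strand == "-" for h in hits
        )

    def test_read_shorter_than_seed(self, index28):
        assert align_read("ACGTACGTAC", index28, AlignmentPolicy.stringent()) == []

    def test_strand_symmetry(self, genome_panel, index28):
        rng = np.random.default_rng(5)
        ref = genome_panel.references[0]
        for _ in range(25):
            start = int(rng.integers(0, len(ref) - 50))
            read = ref.sequence[start : start + 50]
            fwd = align_read(read, index28, AlignmentPolicy.permissive())
            rev = align_read(revcomp(read), index28, AlignmentPolicy.permissive())
            # start is the leftmost forward coordinate regardless of strand,
            # so reverse-complementing flips the strand and keeps the locus
            flip = {"+": "-", "-": "+"}
            mapped = {
                (h.ref_id, h.start, flip[h.strand], h.mismatches_total)
                for h in fwd
            }
            got = {
                (h.ref_id, h.start, h.strand, h.mismatches_total) for h in rev
            }
            assert mapped == got

    def test_monotone_in_tail_budget(self, genome_panel, index28):
        rng = np.random.default_rng(6)
        ref = genome_panel.references[1]
        for _ in range(10):
            start = int(rng.integers(0, len(ref) - 50))
            read = mutate(
                ref.sequence[start : start + 50],
                rng.choice(np.arange(28, 50), size=3, replace=False),
            )
            prev: set = set()
            for tail in (0, 1, 2, 3, 4):
                pol = AlignmentPolicy.stringent(tail_mismatches_max=tail)
                hits = {
                    (h.ref_id, h.start, h.strand)
                    for h in align_read(read, index28, pol)
                }
                assert prev <= hits
                prev = hits


class TestOracleEquivalence:
    @pytest.mark.parametrize("policy_name", ["stringent", "permissive"])
    def test_random_reads_match_bruteforce(
        self, genome_panel, index28, oracle_align, policy_name
    ):
        """Random 50-nt reads vs a 20 kb panel, hit-set identity."""
        policy = getattr(AlignmentPolicy, policy_name)()
        rng = np.random.default_rng(40)
        refs = genome_panel.references
        reads = []
        for i in range(300):
            kind = rng.random()
            ref = refs[int(rng.integers(len(refs)))]
            start = int(rng.integers(0, len(ref) - 50))
            seq = ref.sequence[start : start + 50]
            if kind < 0.35:
                n_mut = int(rng.integers(1, 5))
                seq = mutate(
                    seq, rng.choice(50, size=n_mut, replace=False)
                )
            elif kind < 0.45:
                seq = "".join(rng.choice(list("ACGT"), size=50))
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(seq)
        n_hits = 0
        for i, seq in enumerate(reads):
            got = align_read(seq, index28, policy)
            expected = oracle_align(seq, genome_panel, policy)
            assert got == expected, f"read {i}"
            n_hits += len(got)
        assert n_hits > 150  # the comparison actually exercised hits

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_small_instances_match_bruteforce(self, data, oracle_align):
        ref = generate_genome(1_200, 0.5, seed=data.draw(st.integers(0, 50)),
                              ref_id="h")
        panel = ReferencePanel("p", [ref])
        idx = build_index(panel, 8)
        start = data.draw(st.integers(0, len(ref) - 20))
        seq = ref.sequence[start : start + 20]
        n_mut = data.draw(st.integers(0, 3))
        if n_mut:
            positions = data.draw(
                st.lists(st.integers(0, 19), min_size=n_mut, max_size=n_mut,
                         unique=True)
            )
            seq = mutate(seq, positions)
        if data.draw(st.booleans()):
            seq = revcomp(seq)
        policy = AlignmentPolicy(
            seed_length=8,
            seed_mismatches=data.draw(st.sampled_from([0, 3])),
            tail_mismatches_max=data.draw(st.sampled_from([0, 2, None])),
            total_mismatches_max=data.draw(st.sampled_from([3, None])),
            anchor="any_window",
        )
        assert align_read(seq, idx, policy) == oracle_align(seq, panel, policy)


class TestSubtractHost:
    def test_all_host_sample_fully_removed(self, clean_panels):
        from cfplant import StudyDesign, simulate_study

        host, foreign, _ = clean_panels
        design = StudyDesign(
            n_samples=2, depth_range=(300, 300), fixed_concentration_ppm=0.0,
            error_rate=0.0, seed=50,
        )
        reads, _ = simulate_study(design, host, foreign)
        host_index = build_index(host)
        host_ids, survivors = subtract_host(reads, host_index)
        assert survivors == []
        assert len(host_ids) == len(reads)

    def test_spiked_sample_survivors_are_exactly_foreign(self, clean_panels):
        from cfplant import StudyDesign, simulate_study

        host, foreign, _ = clean_panels
        design = StudyDesign(
            n_samples=3, depth_range=(400, 400), fixed_concentration_ppm=2e5,
            error_rate=0.0, seed=51,
        )
        reads, truth = simulate_study(design, host, foreign)
        host_ids, survivors = subtract_host(reads, build_index(host))
        expected = [r.id for r in reads if r.origin_group == "foreign"]
        assert [r.id for r in survivors] == expected
        assert len(expected) == truth["true_foreign_read_count"].sum()

    def test_four_mismatches_survive_permissive_ceiling(self, genome_panel, index28):
        ref = genome_panel.references[0]
        # exact first-28 window kept so a candidate locus is found, but the
        # 3-mismatch ceiling rejects the alignment
        read4 = SequencingRead("q4", mutate(ref.sequence[500:550], [30, 35, 40, 45]))
        read3 = SequencingRead("q3", mutate(ref.sequence[500:550], [30, 35, 40]))
        host_ids, survivors = subtract_host([read4, read3], index28)
        assert [r.id for r in survivors] == ["q4"]
        assert host_ids == ["q3"]
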
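"""Seed-and-extend alignment over an in-memory k-mer index.

Two alignment policies cover the two stages of foreign-DNA screening:

* ``AlignmentPolicy.permissive()`` — host subtraction.  Candidate loci are
  found through any exact seed-length window of the read (stride 1, both
  strands); an alignment is accepted if it has at most 3 mismatches over the
  full read.  Deliberately generous: a read is discarded as host even if it
  carries sequencing errors or private variants.

* ``AlignmentPolicy.stringent()`` — foreign-genome matching.  The first 28 nt
  of the read must match a reference locus exactly; the remaining bases may
  mismatch at most twice.  This keeps chance matches to short homologous
  stretches out of the foreign counts.

No indels: reads are short (36-100 nt) and gapped chance alignments are
precisely what the stringent policy exists to exclude.  ``N`` never matches
any base.  Coordinates are 0-based half-open internally; SAM export is
1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .synthetic import ReferencePanel, ReferenceSequence, SequencingRead

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentPolicy:
    """Mismatch budgets and candidate-generation rule for one aligner pass.

    ``anchor`` selects how candidate loci are generated and which windows of
    the read must be exact:

    * ``"prefix"``: the first ``seed_length`` bases must align with at most
      ``seed_mismatches`` mismatches (0 in practice, so the exact-prefix
      lookup is exhaustive).
    * ``"any_window"``: any seed-length window of the read (stride 1) may
      serve as the exact anchor.

    ``tail_mismatches_max`` bounds mismatches outside the seed prefix;
    ``total_mismatches_max`` bounds mismatches over the whole read.  ``None``
    means unbounded for that budget.
    """

    seed_length: int = 28
    seed_mismatches: int = 0
    tail_mismatches_max: int | None = 2
    total_mismatches_max: int | None = None
    both_strands: bool = True
    anchor: str = "prefix"

    def __post_init__(self) -> None:
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if self.seed_mismatches < 0:
            raise ValueError("seed_mismatches must be >= 0")
        if self.anchor not in ("prefix", "any_window"):
            raise ValueError("anchor must be 'prefix' or 'any_window'")
        if self.anchor == "prefix" and self.seed_mismatches != 0:
            raise ValueError(
                "prefix anchoring relies on exact seed lookup; seed_mismatches must be 0"
            )

    @classmethod
    def stringent(cls, seed_length: int = 28, tail_mismatches_max: int = 2,
                  both_strands: bool = True) -> "AlignmentPolicy":
        """Exact 28-nt prefix seed, <= 2 mismatches in the tail."""
        return cls(
            seed_length=seed_length,
            seed_mismatches=0,
            tail_mismatches_max=tail_mismatches_max,
            total_mismatches_max=None,
            both_strands=both_strands,
            anchor="prefix",
        )

    @classmethod
    def permissive(cls, seed_length: int = 28, total_mismatches_max: int = 3,
                   both_strands: bool = True) -> "AlignmentPolicy":
        """Any exact seed window as anchor, <= 3 mismatches over the read."""
        return cls(
            seed_length=seed_length,
            seed_mismatches=total_mismatches_max,
            tail_mismatches_max=None,
            total_mismatches_max=total_mismatches_max,
            both_strands=both_strands,
            anchor="any_window",
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One gapless alignment of a read to a reference locus.

    ``start`` is the 0-based offset of the read's leftmost aligned base on
    forward reference coordinates regardless of strand.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str
    mismatches_seed: int
    mismatches_total: int


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer lookup over both strands of every reference in a panel.

    Maps each seed-length substring to a list of ``(ref_id, pos, strand)``
    where ``pos`` is the forward-coordinate start of the k-mer occurrence; a
    ``-`` entry means the k-mer occurs reverse-complemented at that locus.
    K-mers containing N are not indexed.
    """

    def __init__(self, panel: ReferencePanel, seed_length: int = 28):
        self.panel = panel
        self.seed_length = int(seed_length)
        self.skipped_references: list[str] = []
        self._lookup: dict[str, list[tuple[str, int, str]]] = {}
        k = self.seed_length
        for ref in panel:
            seq = ref.sequence
            if len(seq) < k:
                logger.warning(
                    "reference %s shorter than seed length %d; skipped", ref.id, k
                )
                self.skipped_references.append(ref.id)
                continue
            self._add_strand(ref.id, seq, "+")
            self._add_strand(ref.id, seq, "-")

    def _add_strand(self, ref_id: str, seq: str, strand: str) -> None:
        k = self.seed_length
        L = len(seq)
        s = seq if strand == "+" else revcomp(seq)
        lookup = self._lookup
        for q in range(L - k + 1):
            kmer = s[q : q + k]
            if "N" in kmer:
                continue
            pos = q if strand == "+" else L - k - q
            lookup.setdefault(kmer, []).append((ref_id, pos, strand))

    def get(self, kmer: str) -> list[tuple[str, int, str]]:
        return self._lookup.get(kmer, [])

    def __len__(self) -> int:
        return len(self._lookup)


def build_index(panel: ReferencePanel, seed_length: int = 28) -> SeedIndex:
    """Build a :class:`SeedIndex` for a panel."""
    return SeedIndex(panel, seed_length)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _mismatches(read: str, window: str, seed_length: int) -> tuple[int, int]:
    """(seed, total) mismatch counts; N on either side never matches."""
    mm_seed = 0
    mm_total = 0
    for i, (a, b) in enumerate(zip(read, window)):
        if a != b or a == "N":
            mm_total += 1
            if i < seed_length:
                mm_seed += 1
    return mm_seed, mm_total


def align_read(
    read: SequencingRead | str,
    index: SeedIndex,
    policy: AlignmentPolicy,
    *,
    first_hit_only: bool = False,
) -> list[AlignmentHit]:
    """Align one read against the index under a policy.

    Returns all qualifying loci sorted by (ref_id, start, strand), or at most
    one (arbitrary qualifying) hit when ``first_hit_only`` is set — used for
    presence/absence screening where enumerating loci is wasted work.
    Reads shorter than the seed length yield no hits.
    """
    if isinstance(read, SequencingRead):
        read_id, seq = read.id, read.sequence
    else:
        read_id, seq = "", read
    k = policy.seed_length
    L = len(seq)
    if L < k:
        return []

    offsets = (0,) if policy.anchor == "prefix" else range(L - k + 1)
    candidates: set[tuple[str, int, str]] = set()
    for o in offsets:
        kmer = seq[o : o + k]
        for ref_id, p, strand in index.get(kmer):
            if strand == "+":
                start = p - o
            else:
                if not policy.both_strands:
                    continue
                start = p + o + k - L
            candidates.add((ref_id, start, strand))

    hits = []
    for ref_id, start, strand in candidates:
        ref = index.panel[ref_id]
        if start < 0 or start + L > len(ref):
            continue
        window = ref.sequence[start : start + L]
        if strand == "-":
            window = revcomp(window)
        mm_seed, mm_total = _mismatches(seq, window, k)
        mm_tail = mm_total - mm_seed
        if mm_seed > policy.seed_mismatches:
            continue
        if policy.tail_mismatches_max is not None and mm_tail > policy.tail_mismatches_max:
            continue
        if policy.total_mismatches_max is not None and mm_total > policy.total_mismatches_max:
            continue
        if policy.anchor == "any_window":
            # anchor requirement: some window must be exact
            if not _has_exact_window(seq, window, k):
                continue
        hits.append(AlignmentHit(read_id, ref_id, start, strand, mm_seed, mm_total))
        if first_hit_only:
            return hits
    hits.sort(key=lambda h: (h.ref_id, h.start, h.strand))
    return hits


def _has_exact_window(read: str, window: str, k: int) -> bool:
    run = 0
    for a, b in zip(read, window):
        if a == b and a != "N":
            run += 1
            if run >= k:
                return True
        else:
            run = 0
    return False


def align_reads(
    reads: Iterable[SequencingRead],
    index: SeedIndex,
    policy: AlignmentPolicy,
) -> list[AlignmentHit]:
    """Align many reads; concatenated hit lists in input read order."""
    out: list[AlignmentHit] = []
    for r in reads:
        out.extend(align_read(r, index, policy))
    return out


def subtract_host(
    reads: Sequence[SequencingRead],
    host_index: SeedIndex,
    policy: AlignmentPolicy | None = None,
) -> tuple[list[str], list[SequencingRead]]:
    """Remove reads with any permissive hit on the host panel.

    Returns (host read ids, surviving reads in input order).
    """
    if policy is None:
        policy = AlignmentPolicy.permissive()
    host_ids: list[str] = []
    survivors: list[SequencingRead] = []
    for r in reads:
        if align_read(r, host_index, policy, first_hit_only=True):
            host_ids.append(r.id)
        else:
            survivors.append(r)
    return host_ids, survivors


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tstart0\tstrand\tmm_seed\tmm_total\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.ref_id}\t{h.start}\t{h.strand}"
                f"\t{h.mismatches_seed}\t{h.mismatches_total}\n"
            )


def read_hits_tsv(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, ref, start, strand, mseed, mtot = line.rstrip("\n").split("\t")
            hits.append(AlignmentHit(rid, ref, int(start), strand, int(mseed), int(mtot)))
    return hits


def write_sam(
    hits: Iterable[AlignmentHit],
    panel: ReferencePanel,
    reads_by_id: dict[str, SequencingRead],
    path,
) -> None:
    """Minimal SAM export of hits (mandatory columns, @SQ header lines)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref in panel:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
        for h in hits:
            read = reads_by_id[h.read_id]
            seq = read.sequence
            flag = 0
            if h.strand == "-":
                flag = 16
                seq = revcomp(seq)
            fh.write(
                f"{h.read_id}\t{flag}\t{h.ref_id}\t{h.start + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\t"
                f"NM:i:{h.mismatches_total}\n"
            )
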
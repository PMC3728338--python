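"""Read triage, ppm quantification, fraction pooling and coverage profiles.

After host subtraction, reads with a stringent hit on the foreign
(chloroplast) panel are screened against a confounder panel of bacterial and
mammalian genomes: chloroplasts share their rRNA operons with bacteria, so a
foreign-matching read may be of bacterial rather than plant origin.  Reads
are labelled ``plants_only``, ``also_bacteria`` or ``also_mammalia``
accordingly (bacteria take precedence when both match).

Concentration is expressed in ppm — foreign-matching reads per million total
reads.  A read with hits on several foreign references counts once toward
the sample's foreign-read count k but contributes to the pileup of every
reference it hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, ROUND_DOWN, Decimal
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentHit, AlignmentPolicy, SeedIndex, align_read
from .synthetic import ReferenceSequence, SequencingRead

LABELS = ("host", "plants_only", "also_bacteria", "also_mammalia", "unaligned")


# ---------------------------------------------------------------------------
# ppm arithmetic
# ---------------------------------------------------------------------------

def compute_ppm(k: int, N: int, *, decimals: int = 3, mode: str = "half_up") -> float:
    """Foreign reads per million total reads, displayed to ``decimals``.

    ``mode='half_up'`` rounds half away from zero (the default display
    convention); ``mode='truncate'`` drops the excess digits instead, which
    some published tables use.
    """
    if N <= 0:
        raise ValueError("total read count N must be > 0")
    if not (0 <= k <= N):
        raise ValueError("require 0 <= k <= N")
    exact = Decimal(k) * 10**6 / Decimal(N)
    q = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_DOWN
    if mode not in ("half_up", "truncate"):
        raise ValueError("mode must be 'half_up' or 'truncate'")
    return float(exact.quantize(q, rounding=rounding))


def whole_ppm(k: int, N: int) -> int:
    """ppm as a whole number (floor), for in-text figures like '49 ppm'."""
    if N <= 0:
        raise ValueError("total read count N must be > 0")
    return int(Decimal(k) * 10**6 // Decimal(N))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class SampleConcentration:
    """Per-sample (or per-fraction) foreign-DNA concentration summary.

    ``ppm`` and ``detection_limit_ppm`` are display values (3 decimals,
    half-up); ``ppm_exact`` / ``detection_limit_exact`` keep full precision
    for model fitting.  The detection limit is the concentration at which one
    read is expected: 1e6 / N ppm.
    """

    sample_id: str
    total_reads: int
    foreign_reads: int
    fraction: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.foreign_reads <= self.total_reads):
            raise ValueError("require 0 <= foreign_reads <= total_reads")

    @property
    def ppm(self) -> float:
        return compute_ppm(self.foreign_reads, self.total_reads)

    @property
    def ppm_exact(self) -> float:
        return self.foreign_reads / self.total_reads * 1e6

    @property
    def detection_limit_ppm(self) -> float:
        return compute_ppm(1, self.total_reads) if self.total_reads >= 1 else math.inf

    @property
    def detection_limit_exact(self) -> float:
        return 1e6 / self.total_reads


@dataclass
class CoverageProfile:
    """Per-position alignment depth over one reference."""

    ref_id: str
    depth: np.ndarray

    @property
    def positions_covered(self) -> int:
        return int(np.count_nonzero(self.depth))

    @property
    def mean_coverage(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    def smoothed(self, window: int = 1001) -> np.ndarray:
        return smooth_coverage(self, window)


# ---------------------------------------------------------------------------
# Confounder screen
# ---------------------------------------------------------------------------

def cross_screen(
    reads: Sequence[SequencingRead],
    confounder_index: SeedIndex,
    policy: AlignmentPolicy | None = None,
) -> list[ReadClassification]:
    """Label foreign-matching reads by whether they also hit confounders.

    Every input read is assumed to carry at least one foreign hit.  A read
    that also aligns (stringently) to a bacterial confounder is labelled
    ``also_bacteria``; to a mammalian one, ``also_mammalia`` (bacteria take
    precedence when both match); otherwise ``plants_only``.
    """
    if policy is None:
        policy = AlignmentPolicy.stringent()
    groups = {r.id: r.group for r in confounder_index.panel}
    out = []
    for read in reads:
        hits = align_read(read, confounder_index, policy)
        hit_groups = {groups[h.ref_id] for h in hits}
        if "confounder_bacteria" in hit_groups:
            label = "also_bacteria"
        elif "confounder_mammal" in hit_groups:
            label = "also_mammalia"
        else:
            label = "plants_only"
        out.append(ReadClassification(read.id, label))
    return out


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pool_fractions(rows: Sequence[SampleConcentration]) -> SampleConcentration:
    """Pool per-fraction rows of one sample: sum counts, recompute ppm.

    ppm is recomputed from the pooled sums, never averaged across fractions.
    """
    if not rows:
        raise ValueError("need at least one fraction row")
    sample_ids = {r.sample_id for r in rows}
    if len(sample_ids) != 1:
        raise ValueError(f"rows belong to different samples: {sorted(sample_ids)}")
    fractions = [r.fraction for r in rows]
    if len(set(fractions)) != len(fractions):
        raise ValueError("duplicate fraction labels")
    return SampleConcentration(
        sample_id=rows[0].sample_id,
        total_reads=sum(r.total_reads for r in rows),
        foreign_reads=sum(r.foreign_reads for r in rows),
        fraction="pooled",
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def pileup(
    hits: Iterable[AlignmentHit],
    reference: ReferenceSequence,
    read_length: int,
) -> CoverageProfile:
    """Per-position depth over a reference from gapless fixed-length hits."""
    L = len(reference)
    diff = np.zeros(L + 1, dtype=np.int64)
    for h in hits:
        if h.ref_id != reference.id:
            raise ValueError(f"hit on {h.ref_id} passed to pileup of {reference.id}")
        if h.start < 0 or h.start + read_length > L:
            raise ValueError(
                f"hit at {h.start} (+{read_length}) overruns reference of length {L}"
            )
        diff[h.start] += 1
        diff[h.start + read_length] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(ref_id=reference.id, depth=depth)


def smooth_coverage(profile: CoverageProfile | np.ndarray, window: int = 1001) -> np.ndarray:
    """Centered moving average; edge windows truncated to the available span."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    depth = profile.depth if isinstance(profile, CoverageProfile) else np.asarray(profile)
    depth = depth.astype(float)
    if window == 1 or depth.size == 0:
        return depth.copy()
    kernel = np.ones(window)
    sums = np.convolve(depth, kernel, mode="same")
    counts = np.convolve(np.ones_like(depth), kernel, mode="same")
    return sums / counts


def coverage_ratio(
    foreign: CoverageProfile | float, host_mean_coverage: float
) -> float:
    """Foreign-to-host mean-coverage ratio (>1: foreign DNA over-represented)."""
    if host_mean_coverage <= 0:
        raise ValueError("host mean coverage must be > 0")
    fg = foreign.mean_coverage if isinstance(foreign, CoverageProfile) else float(foreign)
    return fg / host_mean_coverage


def write_bedgraph(profile: CoverageProfile, path) -> None:
    """BedGraph (0-based half-open) run-length encoding of the depth track."""
    depth = profile.depth
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.ref_id} coverage"\n')
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        for s, e in zip(starts, ends):
            fh.write(f"{profile.ref_id}\t{s}\t{e}\t{int(depth[s])}\n")
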
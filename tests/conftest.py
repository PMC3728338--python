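"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's seed-index code path: they scan
every (locus, strand) of every reference with numpy array comparisons and
apply the policy's acceptance rule directly, so agreement with the aligner
is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfplant import AlignmentHit, make_panels
from cfplant.align import revcomp


def brute_force_align(read_seq, panel, policy, read_id=""):
    """Exhaustive sliding-window alignment oracle.

    Applies the same acceptance rule as the policy: prefix anchoring requires
    the seed prefix to align within ``seed_mismatches`` and the tail within
    ``tail_mismatches_max``; any-window anchoring requires some exact
    seed-length window plus the total budget.  N never matches.
    """
    L = len(read_seq)
    k = policy.seed_length
    if L < k:
        return []
    read_arr = np.frombuffer(read_seq.encode(), dtype="S1")
    rc_arr = np.frombuffer(revcomp(read_seq).encode(), dtype="S1")
    strands = ["+"] + (["-"] if policy.both_strands else [])
    hits = []
    for ref in panel:
        if len(ref) < L:
            continue
        ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
        for strand in strands:
            probe = read_arr if strand == "+" else rc_arr
            mism = windows != probe[None, :]
            mism |= windows == b"N"
            mism |= (probe == b"N")[None, :]
            if strand == "-":
                mism = mism[:, ::-1]  # read orientation
            total = mism.sum(axis=1)
            seed_mm = mism[:, :k].sum(axis=1)
            ok = seed_mm <= policy.seed_mismatches
            if policy.tail_mismatches_max is not None:
                ok &= (total - seed_mm) <= policy.tail_mismatches_max
            if policy.total_mismatches_max is not None:
                ok &= total <= policy.total_mismatches_max
            if policy.anchor == "any_window":
                match = (~mism).astype(np.int64)
                csum = np.cumsum(match, axis=1)
                wsum = csum[:, k - 1 :].copy()
                wsum[:, 1:] -= csum[:, :-k]
                ok &= (wsum == k).any(axis=1)
            for s in np.flatnonzero(ok):
                hits.append(
                    AlignmentHit(
                        read_id, ref.id, int(s), strand,
                        int(seed_mm[s]), int(total[s]),
                    )
                )
    hits.sort(key=lambda h: (h.ref_id, h.start, h.strand))
    return hits


def brute_force_pileup(hits, ref_length, read_length):
    """Per-position interval-count oracle for coverage pileups."""
    depth = np.zeros(ref_length, dtype=int)
    for h in hits:
        for p in range(h.start, h.start + read_length):
            depth[p] += 1
    return depth


@pytest.fixture(scope="session")
def oracle_align():
    return brute_force_align


@pytest.fixture(scope="session")
def oracle_pileup():
    return brute_force_pileup


@pytest.fixture(scope="session")
def default_panels():
    """One (host, foreign, confounder) panel set shared across tests."""
    return make_panels(seed=11)


@pytest.fixture(scope="session")
def clean_panels():
    """Panels without any conserved-region implants (conserved_fraction 0)."""
    return make_panels(conserved_fraction=0.0, seed=12)
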
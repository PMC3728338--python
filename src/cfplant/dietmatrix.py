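"""Species-by-subject foreign-read matrix, visibility filters and clustering.

If foreign plasma DNA really comes from food, different subjects should be
dominated by different plant species according to their diets, and related
species (same plant family) should co-occur.  This module builds the
species x subject count matrix from read classifications, applies the
visibility filters used for heatmap display (species with at least 50 reads,
subjects with at least 10), and hierarchically clusters rows and columns of
the ln(1+count) matrix so that family structure shows up as contiguous
blocks of leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .align import AlignmentHit
from .quantify import ReadClassification
from .synthetic import SequencingRead

logger = logging.getLogger(__name__)


@dataclass
class DietMatrix:
    """Count matrix with species rows, subject columns and family labels."""

    counts: pd.DataFrame
    families: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("species and subject labels must be unique")
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.families is not None:
            self.families = self.families.reindex(c.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.counts.columns)

    def log_transformed(self) -> pd.DataFrame:
        """ln(1+count), the display/clustering transform."""
        return np.log1p(self.counts.astype(float))

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "species"
        if self.families is not None:
            out.insert(0, "family", self.families)
        out.to_csv(path, sep="\t")


def species_counts(
    reads: Sequence[SequencingRead],
    classifications: Sequence[ReadClassification],
    hits: Sequence[AlignmentHit],
    *,
    include_labels: tuple[str, ...] = ("plants_only",),
    families: Mapping[str, str] | None = None,
    best_hits_only: bool = True,
) -> DietMatrix:
    """Count, per (species, subject), the distinct reads attributed to both.

    A read's attribution set is its best-hit species (fewest total
    mismatches; all tied species count) when ``best_hits_only`` is set,
    otherwise every species it hits.  Only reads whose classification label
    is in ``include_labels`` contribute (``plants_only`` by default; add the
    ``also_*`` labels to include homology-ambiguous reads).
    """
    keep = {c.read_id for c in classifications if c.label in include_labels}
    subject_of = {r.id: r.sample for r in reads}
    hits_by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.read_id in keep:
            hits_by_read.setdefault(h.read_id, []).append(h)

    cells: dict[tuple[str, str], set[str]] = {}
    for read_id, read_hits in hits_by_read.items():
        subject = subject_of.get(read_id, "")
        if best_hits_only:
            best = min(h.mismatches_total for h in read_hits)
            species = {h.ref_id for h in read_hits if h.mismatches_total == best}
        else:
            species = {h.ref_id for h in read_hits}
        for s in species:
            cells.setdefault((s, subject), set()).add(read_id)

    rows = sorted({s for s, _ in cells})
    cols = sorted({j for _, j in cells})
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (s, j), read_ids in cells.items():
        mat.loc[s, j] = len(read_ids)
    fam = None
    if families is not None:
        fam = pd.Series({s: families.get(s, "") for s in rows}, name="family")
    return DietMatrix(counts=mat, families=fam)


def filter_matrix(
    m: DietMatrix,
    min_species_reads: int = 50,
    min_subject_reads: int = 10,
) -> DietMatrix:
    """Keep species rows and subject columns above the visibility thresholds.

    Row and column totals are computed on the unfiltered matrix and the two
    masks are applied jointly, once (no iterative re-filtering).  The
    at-least (>=) convention is used at the thresholds.
    """
    if min_species_reads < 0 or min_subject_reads < 0:
        raise ValueError("thresholds must be >= 0")
    row_ok = m.counts.sum(axis=1) >= min_species_reads
    col_ok = m.counts.sum(axis=0) >= min_subject_reads
    out = m.counts.loc[row_ok, col_ok]
    if out.empty:
        logger.warning("visibility filter removed every row or column")
    fam = m.families.loc[row_ok] if m.families is not None else None
    return DietMatrix(counts=out, families=fam)


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def reordered(self, m: DietMatrix) -> pd.DataFrame:
        return m.counts.loc[self.row_order, self.col_order]


def _linkage(data: np.ndarray) -> np.ndarray:
    d = pdist(data, metric="euclidean")
    return hierarchy.linkage(d, method="average")


def cluster_matrix(m: DietMatrix) -> ClusterResult:
    """Average-linkage hierarchical clustering of rows and columns.

    Works on the ln(1+count) matrix with Euclidean distances; deterministic
    for a given input (SciPy's tie-breaking depends only on the distance
    matrix and input order).
    """
    if m.counts.shape[0] < 2 or m.counts.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    X = m.log_transformed().to_numpy()
    row_Z = _linkage(X)
    col_Z = _linkage(X.T)
    row_order = [m.species[i] for i in hierarchy.leaves_list(row_Z)]
    col_order = [m.subjects[i] for i in hierarchy.leaves_list(col_Z)]
    return ClusterResult(row_order, col_order, row_Z, col_Z)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = walk(node.get_left())
        right = walk(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def family_blocks_contiguous(row_order: Sequence[str], families: Mapping[str, str]) -> bool:
    """True when each family's species occupy one contiguous run of leaves."""
    seq = [families[s] for s in row_order]
    seen: set[str] = set()
    prev = None
    for fam in seq:
        if fam != prev:
            if fam in seen:
                return False
            seen.add(fam)
            prev = fam
    return True


def plot_heatmap(m: DietMatrix, result: ClusterResult | None = None, ax=None):
    """ln(1+count) heatmap, optionally in clustered row/column order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = m.log_transformed()
    if result is not None:
        data = data.loc[result.row_order, result.col_order]
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(data.index)), data.index, fontsize=6)
    ax.set_xticks(range(len(data.columns)), data.columns, fontsize=6, rotation=90)
    ax.figure.colorbar(im, ax=ax, label="ln(1 + reads)")
    return ax
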
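"""Synthetic reference panels and simulated cfDNA sequencing studies.

Circulating cell-free DNA (cfDNA) in plasma is dominated by host (human)
fragments; food-derived chloroplast DNA, when present, appears at parts-per-
million (ppm) concentrations that vary over orders of magnitude between
subjects.  This module generates desk-scale stand-ins for that situation with
full ground truth: random reference genomes grouped into a host panel, a
foreign ("chloroplast") panel and a confounder panel (bacterial / mammalian
homologs carrying an implanted conserved rRNA-like region), plus simulated
sequencing studies in which each sample's foreign-DNA concentration is drawn
from a log-normal distribution and thinned binomially by sequencing depth.

All randomness flows through explicit integer seeds; a fixed seed reproduces
the study byte for byte.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GROUPS = ("host", "foreign", "confounder_bacteria", "confounder_mammal")

#: cfDNA fragment-size fractions: intact (>10 kb), smear, nucleosomal (~200 bp)
FRACTION_LABELS = {1: ">10 kb", 2: "200 bp-10 kb", 3: "~200 bp"}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSequence:
    """One reference genome with panel-level metadata.

    ``family`` is a free-text taxon-family label (e.g. "Brassicaceae") used
    downstream when clustering the species-by-subject diet matrix.
    ``implants`` records conserved regions copied in from another genome as
    dicts with keys ``start`` (position here), ``source_id``, ``source_start``
    and ``length``.
    """

    id: str
    name: str
    group: str
    family: str
    sequence: str
    implants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if len(self.sequence) < 1000:
            raise ValueError("reference sequences must be >= 1000 nt")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferencePanel:
    """A named set of reference sequences with unique ids."""

    name: str
    references: list[ReferenceSequence]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.references]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate reference ids in panel {self.name!r}")
        self._by_id = {r.id: r for r in self.references}

    def __iter__(self):
        return iter(self.references)

    def __len__(self) -> int:
        return len(self.references)

    def __getitem__(self, ref_id: str) -> ReferenceSequence:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.references]

    def write_fasta(self, path) -> None:
        """Write the panel as multi-FASTA, metadata in the description line."""
        records = [
            SeqRecord(
                Seq(r.sequence),
                id=r.id,
                description=f"group={r.group} family={r.family} name={r.name}",
            )
            for r in self.references
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def read_fasta(cls, path, name: str | None = None) -> "ReferencePanel":
        refs = []
        for rec in SeqIO.parse(path, "fasta"):
            meta = _parse_kv(rec.description)
            refs.append(
                ReferenceSequence(
                    id=rec.id,
                    name=meta.get("name", rec.id),
                    group=meta.get("group", "foreign"),
                    family=meta.get("family", ""),
                    sequence=str(rec.seq).upper(),
                )
            )
        return cls(name=name or str(path), references=refs)


@dataclass
class SequencingRead:
    """A single sequencing read with sample / fraction / ground-truth metadata.

    ``origin_group`` / ``origin_ref`` record the simulated source of the read
    (the way read simulators encode truth in read names); they are carried in
    the FASTQ description and never consulted by the analysis stages.
    """

    id: str
    sequence: str
    sample: str = ""
    fraction: int = 0
    origin_group: str = ""
    origin_ref: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class StudyDesign:
    """Parameters of a simulated cfDNA sequencing study.

    Defaults emulate, at desk scale, a many-subject plasma study: per-sample
    depths spanning the real 0.94M-12.8M range scaled down by 100x, read
    length 50 nt, and across-sample foreign-DNA concentrations (in ppm)
    log-normal with location 0.4 and scale 1.6 in ln-ppm units, which puts the
    median near 1.5 ppm and leaves a realistic fraction of samples below their
    detection limit.
    """

    n_samples: int
    depth_range: tuple[int, int] = (9_409, 128_277)
    read_length: int = 50
    concentration_params: tuple[float, float] = (0.4, 1.6)
    fixed_concentration_ppm: float | None = None
    diet_profiles: np.ndarray | None = None
    error_rate: float = 0.005
    conserved_fraction: float = 0.02
    depth_log_uniform: bool = True
    fraction_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("require 0 < min_reads <= max_reads")
        mu, sigma = self.concentration_params
        if sigma <= 0:
            raise ValueError("concentration sigma must be > 0")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.diet_profiles is not None:
            w = np.asarray(self.diet_profiles, dtype=float)
            if w.ndim != 2 or w.shape[0] != self.n_samples:
                raise ValueError("diet_profiles must be (n_samples, n_species)")
            if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0):
                raise ValueError("diet profile rows must be >= 0 and sum to 1")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    length: int,
    gc: float,
    seed: int,
    *,
    ref_id: str = "synth",
    name: str = "synthetic genome",
    group: str = "host",
    family: str = "",
) -> ReferenceSequence:
    """Generate an i.i.d. random genome with the requested GC content.

    Chloroplast genomes are AT-rich (GC ~0.36); bacterial genomes are closer
    to 0.5.  Bases are drawn independently with P(G)+P(C) = ``gc`` split
    evenly between G and C (and A/T likewise).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
    return ReferenceSequence(
        id=ref_id, name=name, group=group, family=family, sequence=seq
    )


def implant_conserved_region(
    foreign: ReferenceSequence,
    confounder: ReferenceSequence,
    region_length: int,
    divergence: float,
    seed: int,
) -> ReferenceSequence:
    """Copy a conserved region from a foreign genome into a confounder.

    Emulates the rRNA operon homology between chloroplasts and bacteria: a
    contiguous stretch of the foreign genome, mutated at per-base rate
    ``divergence``, replaces a same-length stretch of the confounder.  Returns
    a new confounder with the implant recorded in ``implants``.
    """
    if region_length >= min(len(foreign), len(confounder)):
        raise ValueError("region_length must be shorter than both genomes")
    if not (0 <= divergence < 0.3):
        raise ValueError("divergence must be in [0, 0.3)")
    rng = np.random.default_rng(seed)
    src_start = int(rng.integers(0, len(foreign) - region_length + 1))
    dst_start = int(rng.integers(0, len(confounder) - region_length + 1))
    region = np.frombuffer(
        foreign.sequence[src_start : src_start + region_length].encode(), dtype="S1"
    ).copy()
    if divergence > 0:
        mask = rng.random(region_length) < divergence
        n_mut = int(mask.sum())
        if n_mut:
            idx = np.searchsorted(_BASES, region[mask])
            shift = rng.integers(1, 4, size=n_mut)
            region[mask] = _BASES[(idx + shift) % 4]
    new_seq = (
        confounder.sequence[:dst_start]
        + region.tobytes().decode("ascii")
        + confounder.sequence[dst_start + region_length :]
    )
    return ReferenceSequence(
        id=confounder.id,
        name=confounder.name,
        group=confounder.group,
        family=confounder.family,
        sequence=new_seq,
        implants=confounder.implants
        + [
            {
                "start": dst_start,
                "source_id": foreign.id,
                "source_start": src_start,
                "length": region_length,
            }
        ],
    )


def make_panels(
    *,
    n_foreign: int = 8,
    n_conf_bacteria: int = 2,
    n_conf_mammal: int = 1,
    host_length: int = 100_000,
    foreign_length: int = 20_000,
    confounder_length: int = 40_000,
    conserved_fraction: float = 0.02,
    conserved_divergence: float = 0.02,
    families: Sequence[str] = ("Brassicaceae", "Fabaceae", "Solanaceae", "Poaceae"),
    seed: int = 0,
) -> tuple[ReferencePanel, ReferencePanel, ReferencePanel]:
    """Build (host, foreign, confounder) panels for a simulated study.

    Foreign genomes are AT-rich plastome analogs assigned round-robin to
    ``families``; each foreign genome donates a conserved region of length
    ``conserved_fraction * foreign_length`` to a bacterial confounder
    (round-robin), mutated at ``conserved_divergence``.
    """
    rng = np.random.default_rng(seed)

    def sub(lo=0, hi=2**31 - 1):
        return int(rng.integers(lo, hi))

    host = ReferencePanel(
        "host",
        [
            generate_genome(
                host_length, 0.41, sub(), ref_id="host1", name="host genome",
                group="host",
            )
        ],
    )
    foreign_refs = [
        generate_genome(
            foreign_length,
            0.36,
            sub(),
            ref_id=f"plast{i + 1:02d}",
            name=f"plastome {i + 1}",
            group="foreign",
            family=families[i % len(families)],
        )
        for i in range(n_foreign)
    ]
    conf_refs = [
        generate_genome(
            confounder_length, 0.50, sub(), ref_id=f"bact{i + 1:02d}",
            name=f"bacterium {i + 1}", group="confounder_bacteria",
        )
        for i in range(n_conf_bacteria)
    ] + [
        generate_genome(
            confounder_length, 0.42, sub(), ref_id=f"mam{i + 1:02d}",
            name=f"mammal {i + 1}", group="confounder_mammal",
        )
        for i in range(n_conf_mammal)
    ]
    region = int(round(conserved_fraction * foreign_length))
    if region > 0 and n_conf_bacteria > 0:
        for i, fr in enumerate(foreign_refs):
            j = i % n_conf_bacteria
            conf_refs[j] = implant_conserved_region(
                fr, conf_refs[j], region, conserved_divergence, sub()
            )
    return (
        host,
        ReferencePanel("foreign", foreign_refs),
        ReferencePanel("confounder", conf_refs),
    )


# ---------------------------------------------------------------------------
# Diet profile helpers
# ---------------------------------------------------------------------------

def dirichlet_diets(n_samples: int, n_species: int, alpha: float, seed: int) -> np.ndarray:
    """Unstructured per-subject diet mixtures ~ Dirichlet(alpha)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_species, alpha), size=n_samples)


def family_structured_diets(
    families: Sequence[str],
    n_samples: int,
    seed: int,
    *,
    within_family_weight: float = 0.95,
) -> np.ndarray:
    """Diet mixtures in which each subject favours one plant family.

    Subjects are assigned a preferred family in random order;
    ``within_family_weight`` of their mixture mass is spread uniformly over
    that family's species, the rest uniformly over the others.  Produces the
    family-blocked structure seen in diet heatmaps.
    """
    fams = list(families)
    uniq = sorted(set(fams))
    rng = np.random.default_rng(seed)
    prefs = rng.permutation(np.array([uniq[i % len(uniq)] for i in range(n_samples)]))
    n_species = len(fams)
    w = np.empty((n_samples, n_species))
    for i in range(n_samples):
        pref = prefs[i]
        inside = np.array([f == pref for f in fams], dtype=float)
        outside = 1.0 - inside
        row = within_family_weight * inside / inside.sum()
        if outside.sum() > 0:
            row = row + (1 - within_family_weight) * outside / outside.sum()
        else:
            row = inside / inside.sum()
        w[i] = row
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

def _seq_array(ref: ReferenceSequence) -> np.ndarray:
    return np.frombuffer(ref.sequence.encode(), dtype="S1")


def _draw_reads(
    ref_arr: np.ndarray, n: int, read_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n reads uniformly from a genome, strand-symmetric, as (n, L) bytes."""
    starts = rng.integers(0, len(ref_arr) - read_length + 1, size=n)
    idx = starts[:, None] + np.arange(read_length)[None, :]
    reads = ref_arr[idx]
    flip = rng.random(n) < 0.5
    if flip.any():
        rc = reads[flip][:, ::-1]
        code = np.searchsorted(_BASES, rc)
        reads[flip] = np.frombuffer(b"TGCA", dtype="S1")[code]
    return reads


def _apply_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0 or reads.size == 0:
        return
    mask = rng.random(reads.shape) < error_rate
    n_mut = int(mask.sum())
    if n_mut:
        idx = np.searchsorted(_BASES, reads[mask])
        shift = rng.integers(1, 4, size=n_mut)
        reads[mask] = _BASES[(idx + shift) % 4]


def _draw_latents(
    design: StudyDesign, n_species: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (depths, concentrations, foreign counts, per-species counts)."""
    n = design.n_samples
    lo, hi = design.depth_range
    if design.depth_log_uniform:
        depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).round().astype(int)
        depths = np.clip(depths, lo, hi)
    else:
        depths = rng.integers(lo, hi + 1, size=n)
    if design.fixed_concentration_ppm is not None:
        conc = np.full(n, float(design.fixed_concentration_ppm))
    else:
        mu, sigma = design.concentration_params
        conc = np.exp(rng.normal(mu, sigma, size=n))
    p = conc * 1e-6
    if np.any(p > 1):
        logger.warning(
            "%d sample(s) have concentration > 1e6 ppm; capped at 1", int((p > 1).sum())
        )
        p = np.minimum(p, 1.0)
    ks = rng.binomial(depths, p)
    if design.diet_profiles is not None:
        diets = np.asarray(design.diet_profiles, dtype=float)
        if diets.shape[1] != n_species:
            raise ValueError("diet_profiles width != number of foreign species")
    else:
        diets = np.full((n, n_species), 1.0 / n_species)
    per_species = np.vstack(
        [
            rng.multinomial(int(ks[i]), diets[i])
            if ks[i] > 0
            else np.zeros(n_species, dtype=int)
            for i in range(n)
        ]
    )
    return depths, conc, ks, per_species


def simulate_latents(design: StudyDesign, n_species: int = 1) -> pd.DataFrame:
    """Draw only the per-sample latent layer of a study (no reads).

    Returns a frame with sample_id, total_reads, true_concentration_ppm,
    foreign_reads, and per-species count columns ``n_sp01`` ...  Useful for
    moment checks and model-recovery studies at depths where generating
    actual reads would be pointless.
    """
    rng = np.random.default_rng(design.seed)
    depths, conc, ks, per_species = _draw_latents(design, n_species, rng)
    out = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(design.n_samples)],
            "total_reads": depths,
            "true_concentration_ppm": conc,
            "foreign_reads": ks,
        }
    )
    for s in range(n_species):
        out[f"n_sp{s + 1:02d}"] = per_species[:, s]
    return out


def simulate_study(
    design: StudyDesign,
    host_panel: ReferencePanel,
    foreign_panel: ReferencePanel,
) -> tuple[list[SequencingRead], pd.DataFrame]:
    """Simulate a sequencing study; returns (reads, truth table).

    Per sample i: depth N_i is drawn (log-)uniformly from ``depth_range``; the
    true foreign concentration c_i (ppm) is log-normal with the design's
    (mu, sigma) unless ``fixed_concentration_ppm`` overrides it; the foreign
    read count is k_i ~ Binomial(N_i, c_i * 1e-6) (capped at probability 1);
    foreign reads are apportioned over species by the subject's diet profile
    and drawn uniformly (strand-symmetric) from those genomes, the remaining
    reads from the host panel.  Every base is substituted independently with
    probability ``error_rate``.  The truth table records all latent values.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    L = design.read_length
    species = foreign_panel.references
    depths, conc, ks, per_species_all = _draw_latents(design, len(species), rng)

    host_arrs = [_seq_array(r) for r in host_panel.references]
    foreign_arrs = [_seq_array(r) for r in species]

    reads: list[SequencingRead] = []
    truth_rows = []
    for i in range(n):
        sample = f"S{i + 1:03d}"
        N, k = int(depths[i]), int(ks[i])
        per_species = per_species_all[i]
        blocks: list[tuple[np.ndarray, str, str]] = []
        # host reads, split uniformly over host references
        n_host = N - k
        if len(host_arrs) == 1:
            host_split = [n_host]
        else:
            host_split = rng.multinomial(
                n_host, np.full(len(host_arrs), 1 / len(host_arrs))
            )
        for arr, ref, cnt in zip(host_arrs, host_panel.references, host_split):
            if cnt:
                blocks.append((_draw_reads(arr, int(cnt), L, rng), "host", ref.id))
        for arr, ref, cnt in zip(foreign_arrs, species, per_species):
            if cnt:
                blocks.append((_draw_reads(arr, int(cnt), L, rng), "foreign", ref.id))
        fractions = rng.choice([1, 2, 3], size=N, p=design.fraction_probs)
        j = 0
        for block, group, ref_id in blocks:
            _apply_errors(block, design.error_rate, rng)
            for row in block:
                reads.append(
                    SequencingRead(
                        id=f"{sample}_r{j:07d}",
                        sequence=row.tobytes().decode("ascii"),
                        sample=sample,
                        fraction=int(fractions[j]),
                        origin_group=group,
                        origin_ref=ref_id,
                    )
                )
                j += 1
        row = {
            "sample_id": sample,
            "total_reads": N,
            "true_concentration_ppm": float(conc[i]),
            "true_foreign_read_count": k,
            "fractions": ",".join(FRACTION_LABELS[f] for f in (1, 2, 3)),
        }
        for ref, cnt in zip(species, per_species):
            row[f"n_{ref.id}"] = int(cnt)
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return reads, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_kv(description: str) -> dict:
    out = {}
    for tok in description.split():
        if "=" in tok:
            key, val = tok.split("=", 1)
            out[key] = val
    return out


def write_fastq(reads: Iterable[SequencingRead], path) -> None:
    """Write reads as Sanger FASTQ (Phred+33, constant quality 'I')."""

    def records():
        for r in reads:
            rec = SeqRecord(
                Seq(r.sequence),
                id=r.id,
                description=(
                    f"sample={r.sample} fraction={r.fraction} "
                    f"origin={r.origin_group}:{r.origin_ref}"
                ),
            )
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
            yield rec

    SeqIO.write(records(), path, "fastq")


def read_fastq(path) -> list[SequencingRead]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        meta = _parse_kv(rec.description)
        origin = meta.get("origin", ":")
        group, _, ref = origin.partition(":")
        reads.append(
            SequencingRead(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                sample=meta.get("sample", ""),
                fraction=int(meta.get("fraction", 0) or 0),
                origin_group=group,
                origin_ref=ref,
            )
        )
    return reads


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
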
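"""End-to-end orchestration: simulate/load, subtract, match, screen,
quantify, model, cluster — with a run manifest and table-style reports.

The stage order mirrors the screening procedure for foreign DNA in cfDNA
sequencing: host reads are removed with a permissive aligner pass, survivors
are matched stringently against the foreign (chloroplast) panel, matches are
cross-screened against bacterial/mammalian homolog genomes, and the
surviving signal is quantified (ppm per fraction and pooled), profiled
(coverage pileups), modeled (censored log-normal concentration fit with a
finite-sample envelope) and tabulated as a species-by-subject diet matrix.

A run is fully determined by its configuration and seed; rerunning with the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .align import (
    AlignmentPolicy,
    align_read,
    build_index,
    subtract_host,
    write_hits_tsv,
)
from .concentration import (
    CensoredLogNormalFit,
    fit_cdf_curve,
    fit_censored_mle,
    predict_nondetect_fraction,
    simulate_envelope,
)
from .dietmatrix import (
    cluster_matrix,
    filter_matrix,
    linkage_to_newick,
    species_counts,
)
from .quantify import (
    SampleConcentration,
    compute_ppm,
    coverage_ratio,
    cross_screen,
    pileup,
    pool_fractions,
    write_bedgraph,
)
from .synthetic import (
    ReferencePanel,
    SequencingRead,
    StudyDesign,
    make_panels,
    read_fastq,
    simulate_study,
    write_fastq,
    write_truth_table,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "subtract", "match", "screen", "quantify", "model", "cluster",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to (re)run the pipeline deterministically."""

    outdir: str = "cfplant_out"
    # input mode: either a simulation design, or paths to panels + reads
    simulate: bool = True
    design: StudyDesign | None = None
    panel_options: dict = field(default_factory=dict)
    host_fasta: str | None = None
    foreign_fasta: str | None = None
    confounder_fasta: str | None = None
    reads_fastq: str | None = None
    # alignment policy parameters
    seed_length: int = 28
    host_total_mismatches: int = 3
    foreign_tail_mismatches: int = 2
    # quantification / display
    ppm_mode: str = "half_up"
    smooth_window: int = 1001
    # concentration model
    fit_method: str = "censored_mle"
    cdf_cutoff: float | None = None
    n_realizations: int = 300
    # diet matrix
    min_species_reads: int = 50
    min_subject_reads: int = 10
    # global seed: drives simulation and envelope
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        design = None
        if "design" in raw:
            d = dict(raw.pop("design"))
            if "depth_range" in d:
                d["depth_range"] = tuple(d["depth_range"])
            if "concentration_params" in d:
                d["concentration_params"] = tuple(d["concentration_params"])
            design = StudyDesign(**d)
        cfg = cls(design=design, **raw)
        return cfg


@dataclass
class RunReport:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    tallies: dict[str, dict[str, int]]
    per_fraction_table: pd.DataFrame
    pooled_table: pd.DataFrame
    fit: CensoredLogNormalFit | None
    fit_skip_reason: str | None
    coverage_summary: pd.DataFrame
    diet_matrix: Any
    cluster: Any
    truth: pd.DataFrame | None
    outputs: dict[str, str]


def _log_stage(stage: str, n_in: int, n_out: int) -> None:
    logger.info("stage\t%s\tin\t%d\tout\t%d", stage, n_in, n_out)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; writes outputs under ``config.outdir``.

    Any stage failure raises :class:`StageError`; partial outputs are kept
    and a ``FAILED`` marker file names the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        return _run(config, outdir)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        (outdir / "FAILED").write_text(f"{stage}\t{exc}\n")
        raise StageError(stage, exc) from exc


def _run(config: PipelineConfig, outdir: Path) -> RunReport:
    tallies: dict[str, dict[str, int]] = {}
    outputs: dict[str, str] = {}

    def fail(stage: str, exc: BaseException):
        (outdir / "FAILED").write_text(f"{stage}\t{exc}\n")
        return StageError(stage, exc)

    # ---- simulate / load -------------------------------------------------
    truth = None
    try:
        if config.simulate:
            design = config.design or StudyDesign(n_samples=6, seed=config.seed)
            panel_opts = dict(config.panel_options)
            panel_opts.setdefault("seed", design.seed)
            host, foreign, confounder = make_panels(**panel_opts)
            reads, truth = simulate_study(design, host, foreign)
            host.write_fasta(outdir / "host_panel.fasta")
            foreign.write_fasta(outdir / "foreign_panel.fasta")
            confounder.write_fasta(outdir / "confounder_panel.fasta")
            write_fastq(reads, outdir / "reads.fastq")
            write_truth_table(truth, outdir / "truth.tsv")
            outputs.update(
                reads=str(outdir / "reads.fastq"), truth=str(outdir / "truth.tsv")
            )
        else:
            host = ReferencePanel.read_fasta(config.host_fasta, "host")
            foreign = ReferencePanel.read_fasta(config.foreign_fasta, "foreign")
            confounder = (
                ReferencePanel.read_fasta(config.confounder_fasta, "confounder")
                if config.confounder_fasta
                else None
            )
            reads = read_fastq(config.reads_fastq)
        tallies["simulate"] = {"reads_in": 0, "reads_out": len(reads)}
        _log_stage("simulate", 0, len(reads))
    except StageError:
        raise
    except Exception as exc:
        raise fail("simulate", exc)

    read_length = len(reads[0].sequence) if reads else 0

    # ---- subtract host ---------------------------------------------------
    try:
        host_index = build_index(host, config.seed_length)
        permissive = AlignmentPolicy.permissive(
            config.seed_length, config.host_total_mismatches
        )
        host_ids, survivors = subtract_host(reads, host_index, permissive)
        tallies["subtract"] = {"reads_in": len(reads), "reads_out": len(survivors),
                              "host_reads": len(host_ids)}
        _log_stage("subtract", len(reads), len(survivors))
        (outdir / "host_read_ids.txt").write_text("".join(i + "\n" for i in host_ids))
    except Exception as exc:
        raise fail("subtract", exc)

    # ---- match foreign ---------------------------------------------------
    try:
        foreign_index = build_index(foreign, config.seed_length)
        stringent = AlignmentPolicy.stringent(
            config.seed_length, config.foreign_tail_mismatches
        )
        hits = []
        foreign_read_ids = set()
        for r in survivors:
            rh = align_read(r, foreign_index, stringent)
            if rh:
                foreign_read_ids.add(r.id)
                hits.extend(rh)
        matched = [r for r in survivors if r.id in foreign_read_ids]
        tallies["match"] = {"reads_in": len(survivors), "reads_out": len(matched),
                           "hits": len(hits)}
        _log_stage("match", len(survivors), len(matched))
        write_hits_tsv(hits, outdir / "foreign_hits.tsv")
        outputs["hits"] = str(outdir / "foreign_hits.tsv")
    except Exception as exc:
        raise fail("match", exc)

    # ---- cross-screen ----------------------------------------------------
    try:
        if confounder is not None and len(confounder) > 0:
            confounder_index = build_index(confounder, config.seed_length)
            classifications = cross_screen(matched, confounder_index, stringent)
        else:
            from .quantify import ReadClassification

            classifications = [ReadClassification(r.id, "plants_only") for r in matched]
        tallies["screen"] = {
            "reads_in": len(matched),
            "plants_only": sum(c.label == "plants_only" for c in classifications),
            "also_bacteria": sum(c.label == "also_bacteria" for c in classifications),
            "also_mammalia": sum(c.label == "also_mammalia" for c in classifications),
        }
        _log_stage("screen", len(matched), len(classifications))
        with open(outdir / "classifications.tsv", "w") as fh:
            fh.write("read_id\tlabel\n")
            for c in classifications:
                fh.write(f"{c.read_id}\t{c.label}\n")
    except Exception as exc:
        raise fail("screen", exc)

    # ---- quantify + coverage --------------------------------------------
    try:
        label_of = {c.read_id: c.label for c in classifications}
        frac_rows = []
        cell_index: dict[tuple[str, int], dict[str, int]] = {}
        for r in reads:
            cell = cell_index.setdefault(
                (r.sample, r.fraction),
                {"total": 0, "foreign": 0, "bacteria": 0, "mammalia": 0, "plants": 0},
            )
            cell["total"] += 1
            lab = label_of.get(r.id)
            if lab is not None:
                cell["foreign"] += 1
                if lab == "also_bacteria":
                    cell["bacteria"] += 1
                elif lab == "also_mammalia":
                    cell["mammalia"] += 1
                else:
                    cell["plants"] += 1
        for (sample, fraction), cell in sorted(cell_index.items()):
            frac_rows.append(
                {
                    "sample": sample,
                    "fraction": fraction,
                    "total_reads": cell["total"],
                    "chloroplast_reads": cell["foreign"],
                    "ppm": compute_ppm(cell["foreign"], cell["total"],
                                       mode=config.ppm_mode),
                    "bacteria": cell["bacteria"],
                    "mammalia": cell["mammalia"],
                    "plants_only": cell["plants"],
                }
            )
        per_fraction_table, pooled_table = make_report(pd.DataFrame(frac_rows),
                                                       ppm_mode=config.ppm_mode)
        per_fraction_table.to_csv(outdir / "per_fraction_table.tsv", sep="\t",
                                  index=False)
        pooled_table.to_csv(outdir / "pooled_table.tsv", sep="\t", index=False)
        outputs["per_fraction_table"] = str(outdir / "per_fraction_table.tsv")
        outputs["pooled_table"] = str(outdir / "pooled_table.tsv")

        # coverage: pileup on every foreign reference that received hits
        host_bases = len(host_ids) * read_length
        host_len = sum(len(ref) for ref in host)
        host_mean = host_bases / host_len if host_len else 0.0
        cov_rows = []
        hits_by_ref: dict[str, list] = {}
        for h in hits:
            hits_by_ref.setdefault(h.ref_id, []).append(h)
        for ref in foreign:
            ref_hits = hits_by_ref.get(ref.id, [])
            profile = pileup(ref_hits, ref, read_length) if ref_hits else None
            if profile is not None:
                write_bedgraph(profile, outdir / f"coverage_{ref.id}.bedgraph")
            cov_rows.append(
                {
                    "ref_id": ref.id,
                    "length": len(ref),
                    "positions_covered": profile.positions_covered if profile else 0,
                    "mean_coverage": profile.mean_coverage if profile else 0.0,
                    "host_mean_coverage": host_mean,
                    "coverage_ratio": (
                        coverage_ratio(profile, host_mean)
                        if profile is not None and host_mean > 0
                        else float("nan")
                    ),
                }
            )
        coverage_summary = pd.DataFrame(cov_rows)
        coverage_summary.to_csv(outdir / "coverage_summary.tsv", sep="\t", index=False)
        tallies["quantify"] = {
            "samples": pooled_table.shape[0],
            "foreign_reads_total": int(pooled_table["chloroplast_reads"].sum()),
        }
        _log_stage("quantify", len(reads), pooled_table.shape[0])
    except Exception as exc:
        raise fail("quantify", exc)

    # ---- concentration model --------------------------------------------
    fit = None
    fit_skip_reason = None
    try:
        samples = [
            SampleConcentration(
                sample_id=row["sample"],
                total_reads=int(row["total_reads"]),
                foreign_reads=int(row["chloroplast_reads"]),
                fraction="pooled",
            )
            for _, row in pooled_table.iterrows()
        ]
        n_detected = sum(s.foreign_reads > 0 for s in samples)
        if n_detected < 10:
            fit_skip_reason = (
                f"model stage skipped: {n_detected} detected sample(s), need >= 10"
            )
            logger.info(fit_skip_reason)
        else:
            if config.fit_method == "censored_mle":
                fit = fit_censored_mle(samples)
            else:
                cutoff = config.cdf_cutoff
                if cutoff is None:
                    # above the largest per-sample limit no observation is censored
                    cutoff = float(max(s.detection_limit_exact for s in samples))
                fit = fit_cdf_curve(samples, cutoff)
            depths = [s.total_reads for s in samples]
            env = simulate_envelope(
                fit, depths, config.n_realizations, seed=config.seed
            )
            fit.to_frame().to_csv(outdir / "fit_report.tsv", sep="\t", index=False)
            env.to_frame().to_csv(outdir / "envelope.tsv", sep="\t", index=False)
            outputs["fit_report"] = str(outdir / "fit_report.tsv")
            nondetect = predict_nondetect_fraction(fit, depths)
            tallies["model"] = {"n_detected": fit.n_detected,
                                "n_censored": fit.n_censored}
            (outdir / "nondetect_prediction.txt").write_text(f"{nondetect:.6f}\n")
        _log_stage("model", len(samples), 0 if fit is None else 1)
    except Exception as exc:
        raise fail("model", exc)

    # ---- diet matrix -----------------------------------------------------
    matrix = None
    cluster = None
    try:
        families = {ref.id: ref.family for ref in foreign}
        matrix = species_counts(reads, classifications, hits, families=families)
        filtered = filter_matrix(
            matrix, config.min_species_reads, config.min_subject_reads
        )
        filtered.write_tsv(outdir / "diet_matrix.tsv")
        outputs["diet_matrix"] = str(outdir / "diet_matrix.tsv")
        if filtered.counts.shape[0] >= 2 and filtered.counts.shape[1] >= 2:
            cluster = cluster_matrix(filtered)
            (outdir / "species_dendrogram.nwk").write_text(
                linkage_to_newick(cluster.row_linkage, filtered.species) + "\n"
            )
            (outdir / "subject_dendrogram.nwk").write_text(
                linkage_to_newick(cluster.col_linkage, filtered.subjects) + "\n"
            )
        tallies["cluster"] = {
            "species": filtered.counts.shape[0],
            "subjects": filtered.counts.shape[1],
        }
        _log_stage("cluster", matrix.counts.shape[0], filtered.counts.shape[0])
        matrix = filtered
    except Exception as exc:
        raise fail("cluster", exc)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "cfplant_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": _jsonable(config),
        "tallies": tallies,
        "fit_skip_reason": fit_skip_reason,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = str(outdir / "manifest.json")

    return RunReport(
        config=config,
        tallies=tallies,
        per_fraction_table=per_fraction_table,
        pooled_table=pooled_table,
        fit=fit,
        fit_skip_reason=fit_skip_reason,
        coverage_summary=coverage_summary,
        diet_matrix=matrix,
        cluster=cluster,
        truth=truth,
        outputs=outputs,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def make_report(
    per_fraction: pd.DataFrame, *, ppm_mode: str = "half_up"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-fraction and pooled concentration tables.

    ``per_fraction`` needs columns ``sample``, ``fraction``, ``total_reads``,
    ``chloroplast_reads`` (classification count columns ``bacteria`` /
    ``mammalia`` / ``plants_only`` are carried through and summed when
    present).  The pooled table recomputes ppm from pooled counts, never by
    averaging fraction-level ppm values.
    """
    required = {"sample", "fraction", "total_reads", "chloroplast_reads"}
    missing = required - set(per_fraction.columns)
    if missing:
        raise ValueError(f"per-fraction table missing columns: {sorted(missing)}")
    frac = per_fraction.copy()
    if frac.empty:
        cols = list(per_fraction.columns) + (
            ["ppm"] if "ppm" not in per_fraction.columns else []
        )
        pooled_cols = [c for c in cols if c != "fraction"]
        return frac.reindex(columns=cols), pd.DataFrame(columns=pooled_cols)
    frac["ppm"] = [
        compute_ppm(int(k), int(n), mode=ppm_mode)
        for k, n in zip(frac["chloroplast_reads"], frac["total_reads"])
    ]
    dup = frac.duplicated(subset=["sample", "fraction"])
    if dup.any():
        raise ValueError("duplicate (sample, fraction) rows")

    sum_cols = ["total_reads", "chloroplast_reads"] + [
        c for c in ("bacteria", "mammalia", "plants_only") if c in frac.columns
    ]
    pooled = frac.groupby("sample", sort=True)[sum_cols].sum().reset_index()
    pooled["ppm"] = [
        compute_ppm(int(k), int(n), mode=ppm_mode)
        for k, n in zip(pooled["chloroplast_reads"], pooled["total_reads"])
    ]
    order = ["sample", "fraction", "total_reads", "chloroplast_reads", "ppm"] + [
        c for c in ("bacteria", "mammalia", "plants_only") if c in frac.columns
    ]
    frac = frac[order]
    pooled = pooled[[c for c in order if c != "fraction"]]
    return frac, pooled
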
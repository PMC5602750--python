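"""End-to-end driver: filter -> pileup -> call -> annotate -> merge -> RPKM
-> summary, with all tabular outputs written to one directory.

A run is configured either from files (genome FASTA + GFF3 + one SAM per
tissue) or from a :class:`~plastedit.simulate.SimConfig` for a fully
self-contained synthetic demonstration, in which case a recovery report
against the truth table is also produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_sites, annotated_to_frame, neighbor_context
from .calling import CallParams, call_edits, sites_to_frame
from .compare import differential_to_frame, expression_table, merge_tissues
from .errors import ConfigurationError
from .genome import ReferenceGenome, read_gff3
from .pileup import AlignmentFilterParams, build_pileup, filter_alignments, read_sam
from .report import summarize
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full run.

    Exactly one of ``sim`` or (``genome_fasta`` + ``gff3`` +
    ``sam_per_tissue``) must be provided.
    """

    sim: SimConfig | None = None
    genome_fasta: str | None = None
    gff3: str | None = None
    sam_per_tissue: dict[str, str] | None = None
    filter_params: AlignmentFilterParams = field(default_factory=AlignmentFilterParams)
    call_params: CallParams = field(default_factory=CallParams)
    diff_threshold: float = 0.20
    known_sites_tsv: str | None = None

    def validate(self) -> None:
        if self.sim is not None:
            return
        for name in ("genome_fasta", "gff3", "sam_per_tissue"):
            if getattr(self, name) is None:
                raise ConfigurationError(f"missing required configuration field: {name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "sim" in raw:
            sim_kwargs = raw["sim"] or {}
            for key in ("efficiency_range", "tissue_labels", "differential_deltas",
                        "cds_codon_range", "intron_length_range"):
                if key in sim_kwargs and sim_kwargs[key] is not None:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            kwargs["sim"] = SimConfig(**sim_kwargs)
        for key in ("genome_fasta", "gff3", "sam_per_tissue", "diff_threshold",
                    "known_sites_tsv"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filter_params" in raw:
            kwargs["filter_params"] = AlignmentFilterParams(**raw["filter_params"])
        if "call_params" in raw:
            kwargs["call_params"] = CallParams(**raw["call_params"])
        return cls(**kwargs)


def _read_known_sites(path: str) -> set[tuple[int, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (int(r.position), str(r.orientation), str(r.edit_type))
        for r in df.itertuples()
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute every stage and write all outputs under ``outdir``.

    Returns a manifest of the files written.  Any stage failure aborts with
    the stage name attached.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict[str, Path] = {}

    stage = "inputs"
    try:
        truth = None
        if config.sim is not None:
            sim_out = simulate_dataset(config.sim, outdir / "sim")
            genome, features = sim_out.genome, sim_out.features
            truth = sim_out.truth
            sam_paths = {t: str(p) for t, p in sim_out.sam_per_tissue.items()}
            manifest["truth"] = sim_out.truth_tsv
        else:
            genome = ReferenceGenome.from_fasta(config.genome_fasta)
            features = read_gff3(config.gff3)
            sam_paths = dict(config.sam_per_tissue or {})
        tissues = list(sam_paths)

        calls = {}
        pileups = {}
        annotated_frames = {}
        reads_per_tissue = {}
        for tissue, sam in sam_paths.items():
            stage = f"filter[{tissue}]"
            reads = filter_alignments(read_sam(sam), config.filter_params, genome)
            reads_per_tissue[tissue] = reads
            stage = f"pileup[{tissue}]"
            pileups[tissue] = build_pileup(reads, genome)
            stage = f"call[{tissue}]"
            sites = call_edits(pileups[tissue], genome, features, config.call_params)
            calls[tissue] = sites
            path = outdir / f"edits_{tissue}.tsv"
            sites_to_frame(sites).to_csv(path, sep="\t", index=False)
            manifest[f"edits_{tissue}"] = path
            stage = f"annotate[{tissue}]"
            ann = annotate_sites(sites, features, genome)
            annotated_frames[tissue] = annotated_to_frame(ann)
            path = outdir / f"annotated_{tissue}.tsv"
            annotated_frames[tissue].to_csv(path, sep="\t", index=False)
            manifest[f"annotated_{tissue}"] = path
            ctx = neighbor_context(
                [a for a in ann if not a.site.homopolymer_flag], genome
            )
            path = outdir / f"context_{tissue}.tsv"
            ctx.to_csv(path, sep="\t", index=False)
            manifest[f"context_{tissue}"] = path

        stage = "merge"
        diff = merge_tissues(calls, pileups, config.call_params, config.diff_threshold)
        diff_frame = differential_to_frame(diff, tissues)
        path = outdir / "differential.tsv"
        diff_frame.to_csv(path, sep="\t", index=False)
        manifest["differential"] = path

        stage = "rpkm"
        genes = [f for f in features if f.feature_class == "CDS"]
        if genes and all(len(r) > 0 for r in reads_per_tissue.values()):
            expr = expression_table(reads_per_tissue, genes)
            path = outdir / "expression.tsv"
            expr.to_csv(path, sep="\t", index=False)
            manifest["expression"] = path

        stage = "summarize"
        known = (
            _read_known_sites(config.known_sites_tsv)
            if config.known_sites_tsv
            else None
        )
        summary = summarize(annotated_frames, len(genome), known)
        summary.validate()
        counts_path = outdir / "summary_counts.tsv"
        pct_path = outdir / "summary_percentages.json"
        summary.to_files(counts_path, pct_path)
        manifest["summary_counts"] = counts_path
        manifest["summary_percentages"] = pct_path

        if truth is not None:
            stage = "recovery"
            rec = recovery_report(truth, calls, pileups, diff, tissues)
            path = outdir / "recovery.json"
            path.write_text(json.dumps(rec, indent=2) + "\n")
            manifest["recovery"] = path

        stage = "log"
        log = {
            "package_version": __version__,
            "tissues": tissues,
            "filter_params": dataclasses.asdict(config.filter_params),
            "call_params": dataclasses.asdict(config.call_params),
            "diff_threshold": config.diff_threshold,
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        path = outdir / "run_log.json"
        path.write_text(json.dumps(log, indent=2, default=str) + "\n")
        manifest["run_log"] = path
    except ConfigurationError:
        raise
    except Exception as exc:  # annotate failures with the stage name
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


def recovery_report(truth, calls, pileups, diff_records, tissues) -> dict:
    """Score called sites against the planted truth.

    Sensitivity counts truth sites (outside homopolymer masks, truly present
    in a tissue) recovered in that tissue; false positives are calls at
    unplanted, unmasked positions.
    """
    truth_positions = {rec.position for rec in truth}
    genome_masks = {t: pileups[t].genome.homopolymer_mask(6, pad=1) for t in tissues}
    report: dict = {"per_tissue": {}}
    for tissue in tissues:
        mask = genome_masks[tissue]
        called_pos = {s.position for s in calls[tissue] if not s.homopolymer_flag}
        eligible = [
            rec
            for rec in truth
            if rec.true_efficiency.get(tissue, 0.0) >= 0.05
            and not mask[rec.position - 1]
        ]
        found = sum(1 for rec in eligible if rec.position in called_pos)
        false_pos = [
            s.position
            for s in calls[tissue]
            if not s.homopolymer_flag and s.position not in truth_positions
        ]
        within = 0
        comparable = 0
        by_pos = {s.position: s for s in calls[tissue]}
        for rec in eligible:
            s = by_pos.get(rec.position)
            if s is None or s.depth == 0:
                continue
            e = rec.true_efficiency[tissue]
            se = (e * (1 - e) / s.depth) ** 0.5
            comparable += 1
            if abs(s.efficiency - e) <= 3 * se or se == 0:
                within += 1
        report["per_tissue"][tissue] = {
            "truth_sites": len(eligible),
            "recovered": found,
            "sensitivity": found / len(eligible) if eligible else None,
            "false_positives": len(false_pos),
            "efficiency_within_3se": within / comparable if comparable else None,
        }
    by_key_delta = {}
    for rec in truth:
        if len(tissues) == 2:
            e0 = rec.true_efficiency.get(tissues[0], 0.0)
            e1 = rec.true_efficiency.get(tissues[1], 0.0)
            by_key_delta[rec.position] = e0 - e1
    flagged = {r.position for r in diff_records if r.differential_flag}
    if by_key_delta:
        true_diff = [p for p, d in by_key_delta.items() if abs(d) >= 0.25]
        true_null = [p for p, d in by_key_delta.items() if abs(d) < 1e-12]
        report["differential"] = {
            "n_true_differential": len(true_diff),
            "sensitivity": (
                sum(1 for p in true_diff if p in flagged) / len(true_diff)
                if true_diff
                else None
            ),
            "n_true_null": len(true_null),
            "specificity": (
                sum(1 for p in true_null if p not in flagged) / len(true_null)
                if true_null
                else None
            ),
        }
    return report
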
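"""End-to-end orchestration: coverage -> expression -> boundaries ->
co-transcription -> splicing, from one declarative run configuration.

Every stage is a pure function of (inputs, parameters, seed); the combined
report embeds the resolved configuration so that any run can be reproduced
from its output directory alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import __version__
from .annotation import read_annotation, write_results_table
from .boundaries import call_terminus, call_tss, scan_promoter_sequences, slope_profile
from .cotranscription import candidate_pairs, classify_pair
from .coverage import (depth_from_alignments, depth_from_bedgraph,
                       summarize_coverage, zero_coverage_intervals)
from .expression import count_reads_from_depth, expression_table
from .splicing import (ShortExonError, compare_groups, count_junction_reads,
                       splicing_efficiency, splicing_table)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs and stage parameters for one pipeline run."""

    annotation: str
    outdir: str
    boundaries: str | None = None
    fasta: str | None = None
    mask: str | None = None
    sam: str | None = None
    bedgraph_plus: str | None = None
    bedgraph_minus: str | None = None
    junction_sams: dict[str, dict[str, str]] = field(default_factory=dict)
    promoter_seqs: dict[str, str] = field(default_factory=dict)
    # stage parameters
    thresholds: list[int] = field(default_factory=lambda: [1, 2, 5])
    coverage_window: int = 100
    upstream_span: int = 2000
    slope_window: int = 50
    top_n: int = 3
    match_radius: int = 50
    drop_fraction: float = 0.5
    max_distance: int = 2000
    min_separation: int = 150
    tau: float = 0.5
    flank: int = 30
    extension: int = 100
    read_length: int = 89
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.annotation, self.boundaries, self.fasta, self.mask,
                 self.sam, self.bedgraph_plus, self.bedgraph_minus]
        paths += [p for m in self.junction_sams.values() for p in m.values()]
        for p in paths:
            if p is not None and not os.path.exists(p):
                raise PipelineError(f"input file does not exist: {p}")
        if self.sam is None and (self.bedgraph_plus is None or self.bedgraph_minus is None):
            raise PipelineError("need either a SAM file or a bedGraph pair for depth")
        if not (0 < self.tau) or not (0 < self.drop_fraction):
            raise PipelineError("tau and drop_fraction must be positive")


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage, writing per-stage TSVs, a JSON report and a log
    under ``config.outdir``.  Any stage failure aborts with the stage name.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
    }

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    ref, genes, introns, known = stage("annotation")(lambda: read_annotation(
        config.annotation, promoter_table_path=config.boundaries,
        fasta_path=config.fasta, mask_path=config.mask))

    def load_depth():
        if config.sam is not None:
            return depth_from_alignments(config.sam, ref)
        return depth_from_bedgraph(config.bedgraph_plus, config.bedgraph_minus, ref)
    depth = stage("depth")(load_depth)

    def do_coverage():
        summary = summarize_coverage(depth, genes, thresholds=config.thresholds,
                                     window=config.coverage_window)
        zero = zero_coverage_intervals(depth, 0)
        write_results_table(
            [{"statistic": f"frac_ge_{t}", "value": v} for t, v in summary.frac_ge.items()]
            + [{"statistic": "mean_depth_both", "value": summary.mean_depth_both},
               {"statistic": "max_depth", "value": summary.max_depth},
               {"statistic": "mean_depth_intergenic", "value": summary.mean_depth_intergenic}],
            out("coverage_summary.tsv"), float_decimals=4)
        write_results_table([{"strand": s, "start": a, "end": b} for s, a, b in zero],
                            out("zero_coverage.tsv"), columns=["strand", "start", "end"])
        return {"frac_ge": {str(k): v for k, v in summary.frac_ge.items()},
                "mean_depth_both": summary.mean_depth_both,
                "max_depth": summary.max_depth,
                "mean_depth_intergenic": summary.mean_depth_intergenic,
                "n_zero_coverage_intervals": len(zero)}
    report["coverage"] = stage("coverage")(do_coverage)

    def do_expression():
        counts = count_reads_from_depth(depth, genes, read_length=config.read_length)
        table = expression_table(genes, counts, depth)
        write_results_table(
            [{"gene_id": r.gene_id, "reads_mapped": r.reads_mapped,
              "transcript_length": r.transcript_length, "rpkm": r.rpkm}
             for r in table], out("expression.tsv"), float_decimals=2)
        return {"rpkm": {r.gene_id: r.rpkm for r in table
                         if r.rpkm == r.rpkm}}
    report["expression"] = stage("expression")(do_expression)

    def do_boundaries():
        tss_rows, term_rows = [], []
        n_matched = n_with_known = 0
        for g in genes:
            profile = slope_profile(depth, g, upstream_span=config.upstream_span,
                                    window=config.slope_window)
            calls = call_tss(profile, known, genes, top_n=config.top_n,
                             match_radius=config.match_radius)
            has_known = any(b.gene_id == g.gene_id and b.kind == "tss" for b in known)
            if has_known:
                n_with_known += 1
                if any(c.match_status == "matched" for c in calls):
                    n_matched += 1
            tss_rows += [{"gene_id": c.gene_id, "window_start": c.window[0],
                          "window_end": c.window[1], "slope": c.slope, "rank": c.rank,
                          "match_status": c.match_status} for c in calls]
            t = call_terminus(depth, g, downstream_span=config.upstream_span,
                              window=config.slope_window,
                              drop_fraction=config.drop_fraction, genes=genes,
                              known=known, match_radius=config.match_radius)
            term_rows.append({"gene_id": t.gene_id, "drop_position": t.drop_position,
                              "depth_before": t.depth_before,
                              "depth_after": t.depth_after,
                              "match_status": t.match_status})
        write_results_table(tss_rows, out("tss_calls.tsv"), float_decimals=3)
        write_results_table(term_rows, out("terminus_calls.tsv"), float_decimals=2)
        term_matched = sum(1 for r in term_rows if r["match_status"] == "matched")
        return {"tss_genes_matched": n_matched, "tss_genes_with_known": n_with_known,
                "terminus_matched": term_matched,
                "terminus_total": len(term_rows)}
    report["boundaries"] = stage("boundaries")(do_boundaries)

    def do_scan():
        if not config.promoter_seqs or ref.sequence is None:
            return None
        hits = scan_promoter_sequences(ref, sorted(config.promoter_seqs.items()))
        write_results_table([{"label": l, "strand": s, "position": p}
                             for l, s, p in hits], out("promoter_scan.tsv"),
                            columns=["label", "strand", "position"])
        return {"n_hits": len(hits)}
    scan_result = stage("promoter_scan")(do_scan)
    if scan_result is not None:
        report["promoter_scan"] = scan_result

    def do_cotx():
        rows = []
        for a, b, _sep in candidate_pairs(genes, max_distance=config.max_distance):
            call = classify_pair(depth, (a, b), min_separation=config.min_separation,
                                 tau=config.tau)
            rows.append(dataclasses.asdict(call))
        write_results_table(rows, out("cotranscription.tsv"),
                            columns=["gene_a", "gene_b", "separation", "classification",
                                     "intergenic_min_depth", "reference_depth",
                                     "depth_ratio"])
        return {"classifications": {f"{r['gene_a']}|{r['gene_b']}": r["classification"]
                                    for r in rows}}
    report["cotranscription"] = stage("cotranscription")(do_cotx)

    def do_splicing():
        if not config.junction_sams:
            return None
        gene_by_id = {g.gene_id: g for g in genes}
        records, skipped = [], {}
        for intron in introns:
            paths = config.junction_sams.get(intron.gene_id)
            if not paths:
                continue
            try:
                counts = count_junction_reads(
                    paths["unspliced"], paths["spliced"], intron,
                    gene_by_id[intron.gene_id], flank=config.flank,
                    extension=config.extension)
            except ShortExonError as exc:
                skipped[intron.intron_id] = str(exc)
                continue
            records.append(splicing_efficiency(counts, intron.splice_type,
                                               intron.mechanism))
        write_results_table(splicing_table(records), out("splicing.tsv"))
        result: dict[str, Any] = {
            "se": {r.intron_id: r.se for r in records},
            "skipped": skipped,
        }
        for grouping in ("splice_type", "mechanism"):
            groups = {getattr(r, grouping) for r in records}
            if len(groups) >= 2 and len(records) > len(groups):
                f, p, means = compare_groups(records, grouping)
                result[f"anova_{grouping}"] = {"F": f, "p": p, "group_means": means}
        return result
    splicing_result = stage("splicing")(do_splicing)
    if splicing_result is not None:
        report["splicing"] = splicing_result

    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    with open(out("run.log"), "w") as fh:
        fh.write(f"mito-txscape {__version__}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return report
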
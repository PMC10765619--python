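"""End-to-end orchestration: filter -> sweep scan -> IBD -> candidate mining.

Every stage writes its intermediate artifact in a standard text format
(VCF / TSV / BED) so any step can be cross-checked with external tools,
and :func:`run_all` is equivalent to chaining the CLI subcommands on the
same inputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, ibd, popgen, sweep
from .assoc import build_table, fit_freq_trait_regression, read_count_table
from .filtering import FilterConfig, filter_matrix
from .ibd import IBDConfig
from .intervals import GenomicInterval
from .io import PopulationPanel, read_gff3, read_vcf, write_bed, write_vcf
from .popgen import WindowSpec

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    vcf: str
    panel: str | PopulationPanel
    outdir: str
    gff: str | None = None
    assoc_table: str | None = None
    target_pop: str = "S"
    contrast_pops: list[str] = field(default_factory=lambda: ["Y", "BKX"])
    chain: list[str] | None = None  # default: derived from the panel pedigree
    q_sweep: float = 0.05
    chrom_lengths: dict[str, int] | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    ibd: IBDConfig = field(default_factory=IBDConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (("window", WindowSpec), ("filter", FilterConfig), ("ibd", IBDConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full mining strategy; returns the JSON-ready run report.

    Stages: hard filter -> per-contrast window statistics -> per-contrast
    region calling -> multi-contrast intersection -> IBD relations along
    the pedigree chain -> transmitted-interval intersection -> candidate
    mining against the gene models -> optional count-table association.
    Any stage failure aborts with the stage name; artifacts written so far
    are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    panel = (
        cfg.panel
        if isinstance(cfg.panel, PopulationPanel)
        else PopulationPanel.from_yaml(cfg.panel)
    )

    records, matrix, n_skipped = _stage("read")(read_vcf)(cfg.vcf, panel)
    report["stages"]["read"] = {
        "n_records": len(records),
        "n_skipped_non_snp": n_skipped,
    }

    matrix_f, summary, mask = _stage("filter")(filter_matrix)(
        matrix, records, cfg.filter
    )
    kept_records = [r for r, ok in zip(records, mask) if ok]
    write_vcf(outdir / "filtered.vcf", kept_records, panel.samples)
    report["stages"]["filter"] = summary

    regions_by_contrast: dict[str, list[sweep.SweepRegion]] = {}
    for contrast in cfg.contrast_pops:
        table = _stage(f"sweep-stats:{contrast}")(popgen.sweep_table)(
            matrix_f, cfg.target_pop, contrast, cfg.window, cfg.chrom_lengths
        )
        table.to_csv(outdir / f"windows_{contrast}.tsv", sep="\t", index=False)
        regions = _stage(f"sweep-call:{contrast}")(sweep.call_selected_windows)(
            table, cfg.q_sweep
        )
        write_bed([r.interval for r in regions], outdir / f"regions_{contrast}.bed")
        regions_by_contrast[contrast] = regions
        report["stages"][f"sweep:{contrast}"] = {
            "n_windows": len(table),
            "n_regions": len(regions),
        }

    combined = sweep.combine_contrasts(list(regions_by_contrast.values()))
    write_bed([r.interval for r in combined], outdir / "regions_combined.bed")
    report["stages"]["sweep-combined"] = {"n_regions": len(combined)}

    chain = cfg.chain if cfg.chain is not None else panel.chain
    transmitted: list[GenomicInterval] | None
    if len(chain) >= 3:
        segments = []
        relation_sets = []
        for pop_x, pop_y in zip(chain[:-1], chain[1:]):
            pairs = ibd.cross_population_pairs(panel, pop_x, pop_y)
            segs = _stage(f"ibd:{pop_x}-{pop_y}")(ibd.detect_all_segments)(
                matrix_f, pairs, cfg.ibd
            )
            segments.extend(segs)
            relation_sets.append(
                ibd.relation_intervals(
                    segs, pop_x, pop_y, panel, cfg.ibd.lod_keep_quantile
                )
            )
        _write_segments(segments, outdir / "segments.tsv")
        transmitted = ibd.transmitted_intervals(relation_sets)
        if transmitted:
            write_bed(transmitted, outdir / "transmitted.bed")
        report["stages"]["ibd"] = {
            "n_segments": len(segments),
            "n_transmitted_intervals": len(transmitted),
            "chain": chain,
        }
    else:
        transmitted = None
        report["stages"]["ibd"] = {"skipped": True, "reason": "pedigree chain too short"}

    genes = read_gff3(cfg.gff) if cfg.gff else []
    candidates = _stage("mine")(annotate.mine_candidates)(
        combined, transmitted, genes
    )
    _write_candidates(candidates, outdir / "candidates.tsv")
    report["stages"]["mine"] = {
        "n_candidates": len(candidates),
        "genes": sorted({g for c in candidates for g in c.genes}),
    }

    if cfg.assoc_table:
        rows = read_count_table(cfg.assoc_table)
        build_table(rows).to_csv(outdir / "assoc_report.tsv", sep="\t", index=False)
        fit = fit_freq_trait_regression(rows)
        report["stages"]["assoc"] = dataclasses.asdict(fit)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _write_segments(segments, path: Path) -> None:
    pd.DataFrame(
        {
            "sample_a": [s.sample_a for s in segments],
            "sample_b": [s.sample_b for s in segments],
            "chrom": [s.interval.chrom for s in segments],
            "start": [s.interval.start for s in segments],
            "end": [s.interval.end for s in segments],
            "n_markers": [s.n_markers for s in segments],
            "lod": [s.lod for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def _write_candidates(candidates, path: Path) -> None:
    pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in candidates],
            "start": [c.interval.start for c in candidates],
            "end": [c.interval.end for c in candidates],
            "max_fst": [c.max_fst for c in candidates],
            "max_log2_ratio": [c.max_log2_ratio for c in candidates],
            "genes": [",".join(c.genes) for c in candidates],
        }
    ).to_csv(path, sep="\t", index=False)
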
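"""Synthetic data with the statistical structure the pipeline assumes.

The generator produces, from one seed:

* founder populations diverged under the Balding–Nichols model (population
  allele frequencies Beta-distributed around a shared ancestral frequency,
  with variance parameter equal to the target Fst);
* a selective sweep implanted in one population by haplotype
  homogenization — inside the sweep interval a single haplotype is driven
  to frequency ``1 - residual``, collapsing diversity there and raising
  both windowed Fst and the log2 diversity ratio;
* a crossbred pedigree (founderA x founderB -> F1, founderC x F1 -> F2)
  whose offspring carry recombinant haplotypes drawn from the genotyped
  founder pools, with every transmitted founder-haplotype block recorded
  as a ground-truth IBD tract;
* VCF records with INFO metrics drawn inside (or deliberately outside) the
  hard-filter thresholds, with truth-flagged failing records;
* gene models along the chromosome, one of them planted inside the sweep
  (the "causal" gene the full pipeline should recover);
* Table-style genotype-count/trait rows with a linear trait/allele
  frequency relationship for the association module.

Default population sizes (S=20, BKX=10, Y=11, BS=5, DBS=20) mirror a
realistic crossbred-line study so that desk-scale runs carry comparable
sampling noise.  All generators are deterministic given the seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .assoc import GenotypeCountRow
from .intervals import GenomicInterval
from .io import (
    MISSING,
    GeneModel,
    GenotypeMatrix,
    PopulationPanel,
    VariantRecord,
    write_gff3,
    write_vcf,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "1"
    chrom_bp: int = 2_000_000
    n_variants: int = 4000
    # sweep_pop=None (or a population absent from the config) disables the implant

    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"S": 20, "BKX": 10, "Y": 11, "BS": 5, "DBS": 20}
    )
    pedigree: list[tuple[str, str, str]] = field(
        default_factory=lambda: [("S", "BKX", "BS"), ("Y", "BS", "DBS")]
    )
    divergence_fst: float = 0.1
    sweep_pop: str = "S"
    sweep_start: int = 850_000
    sweep_end: int = 1_150_000  # 300-kb implant
    sweep_residual: float = 0.05
    recomb_per_bp: float = 1e-8
    n_genes: int = 10
    gene_bp: int = 30_000
    fail_fraction: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.sweep_start < self.sweep_end <= self.chrom_bp:
            raise ValueError("sweep interval must lie within the chromosome")
        for pop, size in self.pop_sizes.items():
            if size < 2:
                raise ValueError(f"population {pop} needs >= 2 samples")

    @property
    def founder_pops(self) -> list[str]:
        children = {c for _, _, c in self.pedigree}
        return [p for p in self.pop_sizes if p not in children]

    @property
    def sweep_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.sweep_start, self.sweep_end)

    @property
    def causal_gene_interval(self) -> GenomicInterval:
        mid = (self.sweep_start + self.sweep_end) // 2
        return GenomicInterval(
            self.chrom, mid - self.gene_bp // 2, mid + self.gene_bp - self.gene_bp // 2
        )


@dataclass
class IBDTract:
    sample_a: str
    sample_b: str
    start: int
    end: int
    kind: str  # "parent": immediate parent-offspring; "founder": ultimate-founder block

    @property
    def interval(self) -> GenomicInterval:
        # chrom filled by the scenario's single chromosome
        return GenomicInterval("1", self.start, self.end)


@dataclass
class TruthSet:
    sweep_interval: GenomicInterval
    causal_gene: str
    pop_freqs: dict[str, np.ndarray]
    ibd_tracts: list[IBDTract] = field(default_factory=list)
    failing_records: list[int] = field(default_factory=list)

    def tracts_between(self, sample_a: str, sample_b: str, chrom: str) -> list[GenomicInterval]:
        out = []
        for t in self.ibd_tracts:
            if {t.sample_a, t.sample_b} == {sample_a, sample_b}:
                out.append(GenomicInterval(chrom, t.start, t.end))
        return out

    def parent_pairs(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for t in self.ibd_tracts:
            if t.kind == "parent":
                seen.setdefault((t.sample_a, t.sample_b), None)
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "sweep_interval": [
                self.sweep_interval.chrom,
                self.sweep_interval.start,
                self.sweep_interval.end,
            ],
            "causal_gene": self.causal_gene,
            "failing_records": list(map(int, self.failing_records)),
            "ibd_tracts": [
                [t.sample_a, t.sample_b, t.start, t.end, t.kind]
                for t in self.ibd_tracts
            ],
        }


@dataclass
class _PopHaps:
    """Haplotype pool of one population with ancestry bookkeeping."""

    samples: list[str]
    haps: np.ndarray  # int8 (2 * n_samples, n_variants)
    # per haplotype: list of (start_bp, end_bp, ultimate_founder_sample)
    origins: list[list[tuple[int, int, str]]]


@dataclass
class SimResult:
    cfg: SimConfig
    panel: PopulationPanel
    matrix: GenotypeMatrix
    records: list[VariantRecord]
    genes: list[GeneModel]
    truth: TruthSet


# ---------------------------------------------------------------------------
# founders


def _sample_names(pop: str, size: int) -> list[str]:
    return [f"{pop}_{i:02d}" for i in range(size)]


def simulate_founders(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, _PopHaps], dict[str, np.ndarray]]:
    """Positions, founder haplotype pools, and true population frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95); each founder population
    draws site frequencies from Beta with mean equal to the ancestral
    frequency and variance parameter ``divergence_fst`` (Balding–Nichols),
    then haplotypes i.i.d. per site.
    """
    pos = np.sort(rng.choice(cfg.chrom_bp, size=cfg.n_variants, replace=False))
    anc = rng.uniform(0.05, 0.95, size=cfg.n_variants)
    f = cfg.divergence_fst
    pools: dict[str, _PopHaps] = {}
    freqs: dict[str, np.ndarray] = {}
    for pop in cfg.founder_pops:
        size = cfg.pop_sizes[pop]
        if f > 0:
            scale = (1.0 - f) / f
            pf = rng.beta(anc * scale, (1.0 - anc) * scale)
        else:
            pf = anc.copy()
        freqs[pop] = pf
        haps = (rng.random((2 * size, cfg.n_variants)) < pf).astype(np.int8)
        names = _sample_names(pop, size)
        origins = [
            [(0, cfg.chrom_bp, names[h // 2])] for h in range(2 * size)
        ]
        pools[pop] = _PopHaps(samples=names, haps=haps, origins=origins)
    return pos, pools, freqs


def implant_sweep(
    pools: dict[str, _PopHaps],
    pos: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Homogenize the target population's haplotypes inside the sweep.

    Each target haplotype is replaced by a single template haplotype over
    the sweep sites with probability ``1 - sweep_residual``; other
    populations are untouched (bitwise).  With residual 0 the target's
    diversity in the interval is exactly zero.
    """
    pool = pools[cfg.sweep_pop]
    mask = (pos >= cfg.sweep_start) & (pos < cfg.sweep_end)
    template = pool.haps[0, mask].copy()
    for h in range(pool.haps.shape[0]):
        if rng.random() >= cfg.sweep_residual:
            pool.haps[h, mask] = template


# ---------------------------------------------------------------------------
# crossbreeding


def _gamete(
    pool: _PopHaps,
    parent_idx: int,
    pos: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int, str]], str]:
    """One recombinant gamete from a parent individual of the pool.

    Crossover count ~ Poisson(recomb_per_bp * chrom_bp), positions
    uniform; the gamete alternates between the parent's two haplotypes.
    Returns (alleles, ultimate-founder origin blocks, parent sample name).
    """
    parent = pool.samples[parent_idx]
    h0, h1 = pool.haps[2 * parent_idx], pool.haps[2 * parent_idx + 1]
    o = (pool.origins[2 * parent_idx], pool.origins[2 * parent_idx + 1])
    k = rng.poisson(cfg.recomb_per_bp * cfg.chrom_bp)
    cuts = np.sort(rng.integers(1, cfg.chrom_bp, size=k)) if k else np.array([], dtype=int)
    bounds = np.concatenate([[0], np.unique(cuts), [cfg.chrom_bp]]).astype(int)
    cur = int(rng.integers(2))

    alleles = np.empty_like(h0)
    origins: list[tuple[int, int, str]] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if s == e:
            continue
        site_mask = (pos >= s) & (pos < e)
        alleles[site_mask] = (h0 if cur == 0 else h1)[site_mask]
        for os_, oe, founder in o[cur]:
            lo, hi = max(os_, s), min(oe, e)
            if lo < hi:
                origins.append((lo, hi, founder))
        cur = 1 - cur
    return alleles, _merge_origin_blocks(origins), parent


def _merge_origin_blocks(
    blocks: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, str]] = []
    for s, e, f in sorted(blocks):
        if merged and merged[-1][2] == f and merged[-1][1] >= s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e), f)
        else:
            merged.append((s, e, f))
    return merged


def simulate_cross(
    pools: dict[str, _PopHaps],
    pos: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    parent_pop_a: str,
    parent_pop_b: str,
    child_pop: str,
    truth: TruthSet,
) -> None:
    """Create the offspring population and record truth IBD tracts.

    Each offspring receives one recombinant gamete from a random
    individual of each parent population.  Truth records (a) the whole
    chromosome as parent-offspring IBD for each gamete donor, and (b) each
    ultimate-founder haplotype block (so grandparental sharing along the
    chain is represented too).
    """
    n = cfg.pop_sizes[child_pop]
    names = _sample_names(child_pop, n)
    haps = np.empty((2 * n, cfg.n_variants), dtype=np.int8)
    origins: list[list[tuple[int, int, str]]] = []
    for i, child in enumerate(names):
        for side, parent_pop in enumerate((parent_pop_a, parent_pop_b)):
            pool = pools[parent_pop]
            parent_idx = int(rng.integers(len(pool.samples)))
            alleles, blocks, parent = _gamete(pool, parent_idx, pos, cfg, rng)
            haps[2 * i + side] = alleles
            origins.append(blocks)
            truth.ibd_tracts.append(
                IBDTract(child, parent, 0, cfg.chrom_bp, kind="parent")
            )
            for s, e, founder in blocks:
                if founder != parent:
                    truth.ibd_tracts.append(
                        IBDTract(child, founder, s, e, kind="founder")
                    )
    pools[child_pop] = _PopHaps(samples=names, haps=haps, origins=origins)


# ---------------------------------------------------------------------------
# VCF records with INFO metrics

_METRIC_RULES = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


def _passing_info(rng: np.random.Generator) -> dict[str, float]:
    return {
        "QD": float(rng.uniform(2.5, 40.0)),
        "FS": float(min(rng.exponential(5.0), 59.0)),
        "MQ": float(max(rng.normal(55.0, 5.0), 41.0)),
        "MQRankSum": float(np.clip(rng.normal(0.0, 2.0), -12.4, 12.4)),
        "ReadPosRankSum": float(np.clip(rng.normal(0.0, 2.0), -7.9, 7.9)),
    }


def _violating_value(rule: str, rng: np.random.Generator) -> float:
    lo, hi = {
        "QD": (0.0, 1.9),
        "FS": (61.0, 120.0),
        "MQ": (10.0, 39.0),
        "MQRankSum": (-20.0, -13.0),
        "ReadPosRankSum": (-12.0, -8.5),
    }[rule]
    return float(rng.uniform(lo, hi))


def build_records(
    pos: np.ndarray,
    dosage: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: TruthSet,
) -> list[VariantRecord]:
    """Wrap the dosage matrix in VCF records with simulated INFO metrics.

    A ``fail_fraction`` of records gets exactly one violating metric
    (rules cycled deterministically); missing calls are injected at
    ``missing_rate``.  A record is truth-flagged as failing when it
    carries a violating metric or its emitted missing fraction exceeds
    the 20 % missingness ceiling.
    """
    n_sites, n_samples = dosage.shape
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(miss, MISSING, dosage).astype(np.int8)

    n_fail = int(round(cfg.fail_fraction * n_sites))
    fail_idx = set(
        map(int, rng.choice(n_sites, size=n_fail, replace=False))
    ) if n_fail else set()

    records = []
    failing: set[int] = set()
    rule_cycle = 0
    for i in range(n_sites):
        ref_i = int(rng.integers(4))
        alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
        info = _passing_info(rng)
        if i in fail_idx:
            rule = _METRIC_RULES[rule_cycle % len(_METRIC_RULES)]
            rule_cycle += 1
            info[rule] = _violating_value(rule, rng)
            failing.add(i)
        calls = dosage[i]
        if float(np.mean(calls == MISSING)) > 0.2:
            failing.add(i)
        records.append(
            VariantRecord(
                chrom=cfg.chrom,
                pos=int(pos[i]) + 1,
                id=None,
                ref=str(_BASES[ref_i]),
                alt=str(_BASES[alt_i]),
                info=info,
                calls=calls,
            )
        )
    truth.failing_records = sorted(failing)
    return records


# ---------------------------------------------------------------------------
# gene models


def make_genes(cfg: SimConfig) -> tuple[list[GeneModel], str]:
    """Gene models spaced along the chromosome, one planted in the sweep.

    Each gene has four exons; the first and last exon carry short UTRs.
    Returns ``(genes, causal_gene_id)`` with the causal gene centered on
    the sweep midpoint.
    """
    causal_iv = cfg.causal_gene_interval
    spacing = cfg.chrom_bp // cfg.n_genes
    offset = (spacing - cfg.gene_bp) // 2
    spans = []
    for i in range(cfg.n_genes):
        start = i * spacing + offset
        iv = GenomicInterval(cfg.chrom, start, start + cfg.gene_bp)
        if not iv.overlaps(causal_iv):
            spans.append(iv)
    spans.append(causal_iv)
    spans.sort(key=lambda iv: iv.start)

    genes = []
    causal_id = ""
    for i, iv in enumerate(spans):
        gene_id = f"gene_{i + 1:02d}"
        if iv == causal_iv:
            causal_id = gene_id
        genes.append(_four_exon_gene(gene_id, iv, strand="+" if i % 2 == 0 else "-"))
    return genes, causal_id


def _four_exon_gene(gene_id: str, iv: GenomicInterval, strand: str) -> GeneModel:
    length = iv.length
    exon_len = length // 10
    exons = []
    for frac in (0.0, 0.3, 0.6, 0.9):
        s = iv.start + int(frac * length)
        exons.append(GenomicInterval(iv.chrom, s, min(s + exon_len, iv.end)))
    utr = min(60, exon_len // 4)
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = [GenomicInterval(iv.chrom, first.start, first.start + utr)]
        utr3 = [GenomicInterval(iv.chrom, last.end - utr, last.end)]
        cds_bounds = (first.start + utr, last.end - utr)
    else:
        utr5 = [GenomicInterval(iv.chrom, last.end - utr, last.end)]
        utr3 = [GenomicInterval(iv.chrom, first.start, first.start + utr)]
        cds_bounds = (first.start + utr, last.end - utr)
    cds = []
    for e in exons:
        lo, hi = max(e.start, cds_bounds[0]), min(e.end, cds_bounds[1])
        if lo < hi:
            cds.append(GenomicInterval(iv.chrom, lo, hi))
    # trim to a codon-multiple total length
    total = sum(c.length for c in cds)
    trim = total % 3
    if trim:
        last_cds = cds[-1]
        cds[-1] = GenomicInterval(iv.chrom, last_cds.start, last_cds.end - trim)
    return GeneModel(
        gene_id=gene_id,
        interval=iv,
        strand=strand,
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )


# ---------------------------------------------------------------------------
# full scenario


def simulate_scenario(cfg: SimConfig | None = None) -> SimResult:
    """Run the full generator: founders, sweep, crosses, records, genes."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    pos, pools, freqs = simulate_founders(cfg, rng)
    genes, causal_id = make_genes(cfg)
    truth = TruthSet(
        sweep_interval=cfg.sweep_interval,
        causal_gene=causal_id,
        pop_freqs=freqs,
    )
    if cfg.sweep_pop and cfg.sweep_pop in pools:
        implant_sweep(pools, pos, cfg, rng)
    for parent_a, parent_b, child in cfg.pedigree:
        simulate_cross(pools, pos, cfg, rng, parent_a, parent_b, child, truth)

    panel = PopulationPanel.from_dict(
        {
            "populations": {pop: pools[pop].samples for pop in cfg.pop_sizes},
            "pedigree": [list(t) for t in cfg.pedigree],
        }
    )
    columns = []
    for pop in cfg.pop_sizes:
        h = pools[pop].haps
        columns.append((h[0::2] + h[1::2]).T)  # (n_variants, n_samples)
    dosage = np.concatenate(columns, axis=1).astype(np.int8)
    records = build_records(pos, dosage, cfg, rng, truth)
    matrix = GenotypeMatrix.from_records(records, panel)
    return SimResult(
        cfg=cfg, panel=panel, matrix=matrix, records=records, genes=genes, truth=truth
    )


def write_scenario(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write genotypes.vcf, genes.gff3, panel.yaml and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "gff": outdir / "genes.gff3",
        "panel": outdir / "panel.yaml",
        "truth": outdir / "truth.json",
    }
    write_vcf(
        paths["vcf"],
        result.records,
        result.panel.samples,
        contig_lengths={result.cfg.chrom: result.cfg.chrom_bp},
    )
    write_gff3(result.genes, paths["gff"])
    result.panel.to_yaml(paths["panel"])
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth.to_dict(), fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# association-table generator


def simulate_count_table(
    n_pops: int = 21,
    slope: float = -2.0,
    intercept: float = 4.5,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    n_range: tuple[int, int] = (5, 41),
) -> tuple[list[GenotypeCountRow], dict]:
    """Genotype-count rows with a linear trait/allele-frequency relation.

    Per population: A-allele frequency ~ Uniform(0, 0.9), genotype counts
    multinomial under Hardy–Weinberg, and trait mean
    ``intercept + slope * freq_A + Normal(0, noise_sd)`` where ``freq_A``
    is the realized (count-derived) frequency — so in the noiseless limit
    the fitted line recovers slope and intercept exactly.  Returns the
    rows and a truth dict with the frequencies used.
    """
    if n_pops < 5:
        raise ValueError("need at least 5 populations")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    freqs = []
    for i in range(n_pops):
        q_pop = float(rng.uniform(0.0, 0.9))  # population freq of A
        p = 1.0 - q_pop
        n = int(rng.integers(n_range[0], n_range[1]))
        n_cc, n_ca, n_aa = rng.multinomial(n, [p * p, 2 * p * q_pop, q_pop * q_pop])
        q = (2 * n_aa + n_ca) / (2 * n)  # realized sample frequency
        trait = intercept + slope * q + float(rng.normal(0.0, noise_sd))
        freqs.append(q)
        rows.append(
            GenotypeCountRow(
                population=f"pop_{i + 1:02d}",
                n=n,
                n_CC=int(n_cc),
                n_CA=int(n_ca),
                n_AA=int(n_aa),
                trait_mean=trait,
            )
        )
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd, "freq_A": freqs}
    return rows, truth
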
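"""Readers and writers for VCF, BED, GFF3 and the in-memory genotype matrix.

Only biallelic SNPs enter the genotype matrix; genotype dosage is the count
of ALT alleles per diploid sample (0/1/2) with ``-1`` marking a missing
call.  Missing calls are never imputed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from cyvcf2 import VCF

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

MISSING = -1

#: INFO metrics carried through for hard filtering.
INFO_METRICS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    pass


class PanelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# panel / pedigree


@dataclass
class PopulationPanel:
    """Ordered sample IDs, their population labels, and the pedigree chain.

    The pedigree is an ordered list of ``(parentA, parentB, offspring)``
    population triples, e.g. ``[("S", "BKX", "BS"), ("Y", "BS", "DBS")]``
    for a three-way crossbred line.
    """

    samples: list[str]
    population_of: dict[str, str]
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.population_of]
        if missing:
            raise PanelError(f"samples without population label: {missing[:5]}")
        pops = set(self.population_of.values())
        for triple in self.pedigree:
            for p in triple:
                if p not in pops:
                    raise PanelError(f"pedigree population {p!r} not in panel")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.population_of[s] == population]

    def indices_of(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.population_of[s] == population],
            dtype=np.intp,
        )

    @property
    def chain(self) -> list[str]:
        """Population chain implied by the pedigree (founder -> ... -> terminal).

        For ``[(S, BKX, BS), (Y, BS, DBS)]`` the transmission chain of
        interest is ``[S, BS, DBS]``: the first cross's first parent, then
        each successive offspring.
        """
        if not self.pedigree:
            return []
        chain = [self.pedigree[0][0]]
        for _, _, child in self.pedigree:
            chain.append(child)
        return chain

    @classmethod
    def from_dict(cls, cfg: dict) -> "PopulationPanel":
        pops: dict[str, str] = {}
        samples: list[str] = []
        for pop, names in cfg["populations"].items():
            for name in names:
                samples.append(name)
                pops[name] = pop
        pedigree = [tuple(t) for t in cfg.get("pedigree", [])]
        return cls(samples=samples, population_of=pops, pedigree=pedigree)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationPanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        populations: dict[str, list[str]] = {}
        for s in self.samples:
            populations.setdefault(self.population_of[s], []).append(s)
        return {"populations": populations, "pedigree": [list(t) for t in self.pedigree]}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# variant records and the genotype matrix


@dataclass
class VariantRecord:
    """One biallelic SNP as read from (or written to) a VCF.

    ``pos`` is the 1-based VCF coordinate; everything downstream of I/O
    uses 0-based positions (``pos0``).  ``calls`` holds per-sample ALT
    dosage in panel order, ``-1`` for missing.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str
    info: dict[str, float]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VcfParseError(f"ref == alt at {self.chrom}:{self.pos}")
        self.calls = np.asarray(self.calls, dtype=np.int8)

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.calls == MISSING))


@dataclass
class GenotypeMatrix:
    """Diploid ALT-dosage matrix (variants x samples) plus the panel.

    Positions are 0-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos0: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # int8, (n_variants, n_samples), MISSING = -1
    panel: PopulationPanel

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos0 = np.asarray(self.pos0, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n = len(self.pos0)
        if self.dosage.shape != (n, len(self.panel.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({n}, {len(self.panel.samples)})"
            )
        for c in self.chromosomes:
            p = self.pos0[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos0)

    @property
    def n_samples(self) -> int:
        return len(self.panel.samples)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return np.asarray(self.chrom == chrom)

    def take_rows(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos0=self.pos0[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            panel=self.panel,
        )

    def pop_dosage(self, population: str) -> np.ndarray:
        """Dosage columns of one population, (n_variants, n_pop_samples)."""
        return self.dosage[:, self.panel.indices_of(population)]

    def alt_freqs(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site ALT allele frequency over called genotypes (NaN if none)."""
        d = self.dosage if sample_idx is None else self.dosage[:, sample_idx]
        called = d >= 0
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    @classmethod
    def from_records(
        cls, records: Sequence[VariantRecord], panel: PopulationPanel
    ) -> "GenotypeMatrix":
        n = len(records)
        dosage = np.full((n, len(panel.samples)), MISSING, dtype=np.int8)
        for i, r in enumerate(records):
            dosage[i] = r.calls
        return cls(
            chrom=np.array([r.chrom for r in records], dtype=object),
            pos0=np.array([r.pos0 for r in records], dtype=np.int64),
            ref=np.array([r.ref for r in records], dtype=object),
            alt=np.array([r.alt for r in records], dtype=object),
            dosage=dosage,
            panel=panel,
        )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path, panel: PopulationPanel
) -> tuple[list[VariantRecord], GenotypeMatrix, int]:
    """Read a VCF, keeping biallelic SNPs only.

    Returns ``(records, matrix, n_skipped)`` where ``n_skipped`` counts
    multi-allelic and indel records.  Dosage columns follow panel order
    regardless of VCF header order; phase (``|`` vs ``/``) is ignored.
    """
    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    absent = [s for s in panel.samples if s not in header_samples]
    if absent:
        raise PanelError(f"panel samples absent from VCF header: {absent[:5]}")
    order = np.array([header_samples.index(s) for s in panel.samples], dtype=np.intp)

    records: list[VariantRecord] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in _BASES or var.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        info = {}
        for key in INFO_METRICS:
            val = var.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        # gts012=True: 0/1/2 ALT dosage, 3 = missing
        calls = np.asarray(var.gt_types, dtype=np.int8)[order]
        calls[calls == 3] = MISSING
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID,
                ref=var.REF,
                alt=var.ALT[0],
                info=info,
                calls=calls,
            )
        )
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-SNP/multi-allelic records", n_skipped)
    matrix = GenotypeMatrix.from_records(records, panel)
    return records, matrix, n_skipped


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | Path,
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write biallelic SNP records as an uncompressed VCF v4.2 text file."""
    contigs = contig_lengths or {}
    if not contigs:
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepibd\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key in INFO_METRICS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in records:
            info = ";".join(f"{k}={v:.4g}" for k, v in r.info.items()) or "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in r.calls)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id or '.'}\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED5 file into 0-based half-open intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise VcfParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise VcfParseError(f"{path}:{lineno}: start >= end")
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            out.append(GenomicInterval(chrom, start, end, score=score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (or BED5 when a score is present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{iv.score:.6g}\n")


# ---------------------------------------------------------------------------
# GFF3 / gene models


@dataclass
class GeneModel:
    """One gene reduced to its representative (longest spliced) transcript.

    Intervals are 0-based half-open, exons sorted in genomic order whatever
    the strand.  ``cds_sequence`` (coding orientation, length divisible by
    3) is optional and only needed for codon-effect annotation.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    def cds_offset_of(self, chrom: str, pos0: int) -> int | None:
        """Within-CDS offset of a genomic position, in coding orientation."""
        if chrom != self.interval.chrom:
            return None
        offset = 0
        for iv in self.cds:
            if iv.start <= pos0 < iv.end:
                plus_offset = offset + (pos0 - iv.start)
                if self.strand == "+":
                    return plus_offset
                return self.cds_length - 1 - plus_offset
            offset += iv.length
        return None

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start))
        return out


def gff_to_internal(start_1based: int, end_closed: int) -> tuple[int, int]:
    """GFF3 (1-based, closed) -> internal (0-based, half-open).

    Length is preserved: ``end - start == end_closed - start_1based + 1``.
    """
    return start_1based - 1, end_closed


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


_UTR5_TYPES = {"five_prime_UTR", "5'-UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3'-UTR", "three_prime_utr"}
_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models, one per gene via its longest spliced transcript."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = [
            t for tt in _TRANSCRIPT_TYPES for t in db.children(gene, featuretype=tt)
        ]
        if not transcripts:
            log.warning("gene %s has no transcript; skipped", gene.id)
            continue

        def spliced_length(t) -> int:
            exons = list(db.children(t, featuretype="exon"))
            if not exons:
                return t.end - t.start + 1
            return sum(e.end - e.start + 1 for e in exons)

        best = max(transcripts, key=spliced_length)
        chrom = gene.seqid
        gs, ge = gff_to_internal(gene.start, gene.end)

        def child_ivs(featuretype: str | set[str]) -> list[GenomicInterval]:
            types = [featuretype] if isinstance(featuretype, str) else list(featuretype)
            ivs = []
            for tt in types:
                for f in db.children(best, featuretype=tt):
                    s, e = gff_to_internal(f.start, f.end)
                    ivs.append(GenomicInterval(chrom, s, e))
            return sorted(ivs, key=lambda iv: iv.start)

        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=GenomicInterval(chrom, gs, ge),
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=child_ivs("exon"),
                cds=child_ivs("CDS"),
                utr5=child_ivs(_UTR5_TYPES),
                utr3=child_ivs(_UTR3_TYPES),
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal single-transcript GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            chrom = g.interval.chrom
            gs, ge = internal_to_gff(g.interval.start, g.interval.end)
            fh.write(
                f"{chrom}\t.\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{chrom}\t.\tmRNA\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for kind, ivs in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for k, iv in enumerate(ivs, 1):
                    s, e = internal_to_gff(iv.start, iv.end)
                    frame = "0" if kind == "CDS" else "."
                    fh.write(
                        f"{chrom}\t.\t{kind}\t{s}\t{e}\t.\t{g.strand}\t{frame}\t"
                        f"ID={tid}.{kind}{k};Parent={tid}\n"
                    )
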
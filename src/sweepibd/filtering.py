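"""GATK-style hard filtering and SNP region/effect classification.

The hard-filter thresholds are the conventional GATK SNP defaults
(QD > 2, FS < 60, MQ > 40, MQRankSum > -12.5, ReadPosRankSum > -8) plus a
missingness rule matching ``vcftools --max-missing 0.8``: a site fails when
more than 20 % of its genotype calls are missing.  An INFO metric that is
absent from a record does not fail that rule — GATK leaves the rank-sum
annotations undefined at sites without heterozygotes, and discarding such
records would be over-aggressive.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .io import GeneModel, GenotypeMatrix, VariantRecord

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAIN = "stopGain"
STOP_LOSS = "stopLoss"

REGION_CATEGORIES = (
    "exonic",
    "splicing",
    "utr5",
    "utr3",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)


class AnnotationError(ValueError):
    pass


@dataclass
class FilterConfig:
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


#: rule name -> (INFO key, config attr, comparison); "lt" fails when value < threshold
_RULES = (
    ("QD", "QD", "qd_min", "lt"),
    ("FS", "FS", "fs_max", "gt"),
    ("MQ", "MQ", "mq_min", "lt"),
    ("MQRankSum", "MQRankSum", "mqranksum_min", "lt"),
    ("ReadPosRankSum", "ReadPosRankSum", "readposranksum_min", "lt"),
)

RULE_NAMES = tuple(r[0] for r in _RULES) + ("missingness",)


def hard_filter(
    record: VariantRecord, cfg: FilterConfig | None = None
) -> tuple[bool, list[str]]:
    """Adjudicate one record; returns ``(passed, failed_rule_names)``.

    Total function: never raises.  Monotone in the thresholds — relaxing
    any threshold can only turn fails into passes.
    """
    cfg = cfg or FilterConfig()
    failed: list[str] = []
    for rule, key, attr, cmp in _RULES:
        val = record.info.get(key)
        if val is None:
            continue
        threshold = getattr(cfg, attr)
        if (cmp == "lt" and val < threshold) or (cmp == "gt" and val > threshold):
            failed.append(rule)
    if record.missing_fraction > cfg.max_missing_fraction:
        failed.append("missingness")
    return (not failed, failed)


def filter_matrix(
    matrix: GenotypeMatrix,
    records: Sequence[VariantRecord],
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, dict[str, int], np.ndarray]:
    """Drop rows failing the hard filter.

    Returns the filtered matrix, a per-rule fail-count summary (plus
    ``n_input``/``n_retained``), and the boolean pass mask over input rows.
    """
    if len(records) != matrix.n_variants:
        raise ValueError(
            f"records ({len(records)}) not parallel to matrix rows "
            f"({matrix.n_variants})"
        )
    cfg = cfg or FilterConfig()
    mask = np.zeros(matrix.n_variants, dtype=bool)
    summary = {name: 0 for name in RULE_NAMES}
    for i, rec in enumerate(records):
        ok, failed = hard_filter(rec, cfg)
        mask[i] = ok
        for rule in failed:
            summary[rule] += 1
    summary["n_input"] = matrix.n_variants
    summary["n_retained"] = int(mask.sum())
    return matrix.take_rows(np.flatnonzero(mask)), summary, mask


# ---------------------------------------------------------------------------
# region / effect classification

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def codon_effect(
    cds_sequence: str, offset: int, ref: str, alt: str, strand: str = "+"
) -> str:
    """Coding effect of a SNP under the standard genetic code.

    ``cds_sequence`` is the spliced CDS in coding orientation; ``offset``
    is the 0-based position within it (already in coding orientation);
    ``ref``/``alt`` are the alleles on the + genomic strand and are
    complemented for minus-strand genes.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise AnnotationError(f"CDS length {len(cds)} not divisible by 3")
    if not 0 <= offset < len(cds):
        raise AnnotationError(f"offset {offset} outside CDS of length {len(cds)}")
    if strand == "-":
        ref, alt = _COMPLEMENT[ref.upper()], _COMPLEMENT[alt.upper()]
    else:
        ref, alt = ref.upper(), alt.upper()
    if cds[offset] != ref:
        raise AnnotationError(
            f"reference mismatch at CDS offset {offset}: CDS has "
            f"{cds[offset]}, record says {ref}"
        )
    start = 3 * (offset // 3)
    codon = cds[start : start + 3]
    mutated = codon[: offset % 3] + alt + codon[offset % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return SYNONYMOUS
    if aa_alt == "*":
        return STOP_GAIN
    if aa_ref == "*":
        return STOP_LOSS
    return NONSYNONYMOUS


def _in_any(pos0: int, ivs) -> bool:
    return any(iv.start <= pos0 < iv.end for iv in ivs)


def _gene_category(
    gene: GeneModel, pos0: int, ref: str, alt: str, splice_bp: int
) -> tuple[str, str | None] | None:
    """Category for a position inside the gene span, else None."""
    iv = gene.interval
    if not (iv.start <= pos0 < iv.end):
        return None
    if _in_any(pos0, gene.cds):
        effect = None
        if gene.cds_sequence is not None:
            offset = gene.cds_offset_of(iv.chrom, pos0)
            if offset is not None:
                effect = codon_effect(
                    gene.cds_sequence, offset, ref, alt, gene.strand
                )
        return "exonic", effect
    for intron in gene.introns():
        if (
            intron.start <= pos0 < min(intron.start + splice_bp, intron.end)
            or max(intron.end - splice_bp, intron.start) <= pos0 < intron.end
        ):
            return "splicing", None
    if _in_any(pos0, gene.utr5):
        return "utr5", None
    if _in_any(pos0, gene.utr3):
        return "utr3", None
    return "intronic", None


def classify_region(
    record: VariantRecord,
    genes: Sequence[GeneModel],
    updown_bp: int = 5000,
    splice_bp: int = 2,
) -> tuple[str, str | None]:
    """Assign one region category (and coding effect where applicable).

    Priority: exonic > splicing > utr5 > utr3 > intronic > upstream >
    downstream > intergenic.  Every SNP receives exactly one category.
    """
    pos0 = record.pos0
    rank = {c: i for i, c in enumerate(REGION_CATEGORIES)}
    best: tuple[str, str | None] | None = None

    for gene in genes:
        if gene.interval.chrom != record.chrom:
            continue
        hit = _gene_category(gene, pos0, record.ref, record.alt, splice_bp)
        if hit is None:
            # flanking regions, oriented by strand
            iv = gene.interval
            before = iv.start - updown_bp <= pos0 < iv.start
            after = iv.end <= pos0 < iv.end + updown_bp
            if before or after:
                if gene.strand == "+":
                    cat = "upstream" if before else "downstream"
                else:
                    cat = "downstream" if before else "upstream"
                hit = (cat, None)
        if hit is not None and (best is None or rank[hit[0]] < rank[best[0]]):
            best = hit
    return best if best is not None else ("intergenic", None)
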
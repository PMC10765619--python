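"""Candidate mining: sweep regions x transmitted IBD intervals x genes."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval, intersect_intervals
from .io import GeneModel
from .sweep import SweepRegion


@dataclass
class CandidateRegion:
    """An interval supported by both a selective sweep and transmitted IBD.

    ``genes`` lists every gene whose span (TSS to TES, not exon-restricted)
    overlaps the interval by at least 1 bp; a region with no overlapping
    gene is retained with an empty list.
    """

    interval: GenomicInterval
    max_fst: float
    max_log2_ratio: float
    genes: list[str]


def gene_overlap(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> list[str]:
    """IDs of genes whose span overlaps the interval (>= 1 bp), by start.

    Half-open coordinates: a gene exactly book-ended with the interval does
    not overlap.
    """
    hits = [g for g in genes if g.interval.overlaps(interval)]
    hits.sort(key=lambda g: g.interval.start)
    return [g.gene_id for g in hits]


def mine_candidates(
    sweep_regions: Sequence[SweepRegion],
    transmitted: Sequence[GenomicInterval] | None,
    genes: Sequence[GeneModel],
) -> list[CandidateRegion]:
    """Intersect sweep regions with transmitted IBD intervals and annotate.

    With ``transmitted=None`` (no pedigree available) the sweep regions
    themselves are annotated.  Statistics on each candidate come from the
    overlapping source sweep regions (max over them).
    """
    if transmitted is None:
        pieces = [r.interval for r in sweep_regions]
    else:
        pieces = intersect_intervals(
            [r.interval for r in sweep_regions], transmitted
        )
    out: list[CandidateRegion] = []
    for iv in pieces:
        sources = [r for r in sweep_regions if r.interval.overlaps(iv)]
        out.append(
            CandidateRegion(
                interval=iv,
                max_fst=max(r.max_fst for r in sources),
                max_log2_ratio=max(r.max_log2_ratio for r in sources),
                genes=gene_overlap(iv, genes),
            )
        )
    return out
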
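"""Pairwise IBD segment detection, LOD scoring, and pedigree transmission.

Candidate segments are maximal runs of consecutive jointly-called markers
containing no opposite-homozygote site (the IBS-exclusion criterion: two
individuals sharing a chromosome identically by descent can never be
opposite homozygotes, barring genotyping error).  Each run is scored with
the classical one-shared-allele LOD — the log10 ratio of the genotype-pair
likelihood given one allele shared IBD versus independent Hardy–Weinberg
draws — and runs must clear marker-count, physical-length and positive-LOD
floors.  Population-to-population IBD intervals are the union of surviving
segments after keeping the top fraction by LOD (default the top half),
and transmission along a pedigree chain is the base-pair intersection of
adjacent-relation intervals.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, intersect_many, merge_intervals
from .io import GenotypeMatrix, PopulationPanel


@dataclass
class IBDConfig:
    min_markers: int = 50
    min_bp: int = 100_000
    err: float = 0.001  # genotyping-error floor for the impossible cell
    lod_keep_quantile: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.err < 0.5:
            raise ValueError("err must be in (0, 0.5)")
        if not 0.0 < self.lod_keep_quantile <= 1.0:
            raise ValueError("lod_keep_quantile must be in (0, 1]")


@dataclass
class IBDSegment:
    sample_a: str
    sample_b: str
    interval: GenomicInterval
    n_markers: int
    lod: float


def pooled_alt_freqs(matrix: GenotypeMatrix) -> np.ndarray:
    """ALT frequencies over the whole analysis panel (equal sample weight)."""
    return matrix.alt_freqs()


def _site_lod_terms(
    dos_a: np.ndarray, dos_b: np.ndarray, alt_freqs: np.ndarray, err: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site log10 likelihood-ratio terms and the usable-site mask.

    The IBD1 joint table, with p the REF and q the ALT frequency
    (A = REF allele, a = ALT allele):

    ==========  =========
    pair        P | IBD1
    ==========  =========
    (AA, AA)    p^3
    (AA, Aa)    p^2 q
    (Aa, Aa)    p q
    (Aa, aa)    p q^2
    (aa, aa)    q^3
    (AA, aa)    0 -> err
    ==========  =========

    The null is the product of Hardy–Weinberg marginals.  Sites with a
    missing call or an allele frequency outside (0, 1) are skipped.
    """
    q = np.asarray(alt_freqs, dtype=float)
    p = 1.0 - q
    usable = (dos_a >= 0) & (dos_b >= 0) & (q > 0.0) & (q < 1.0) & np.isfinite(q)

    qs = np.where(usable, q, 0.5)  # placeholder freq to keep logs finite
    ps = 1.0 - qs
    single = np.stack([ps**2, 2.0 * ps * qs, qs**2])  # genotype marginals
    joint = np.empty((3, 3, len(qs)))
    joint[0, 0] = ps**3
    joint[0, 1] = joint[1, 0] = ps**2 * qs
    joint[1, 1] = ps * qs
    joint[1, 2] = joint[2, 1] = ps * qs**2
    joint[2, 2] = qs**3
    joint[0, 2] = joint[2, 0] = err

    ia = np.where(usable, dos_a, 0)
    ib = np.where(usable, dos_b, 0)
    idx = np.arange(len(qs))
    terms = (
        np.log10(joint[ia, ib, idx])
        - np.log10(single[ia, idx])
        - np.log10(single[ib, idx])
    )
    return np.where(usable, terms, 0.0), usable


def segment_lod(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    alt_freqs: np.ndarray,
    err: float = 0.001,
) -> float:
    """Sum of per-site IBD1-vs-independence log10 ratios; symmetric in a/b."""
    da = np.asarray(dosages_a)
    db = np.asarray(dosages_b)
    if da.shape != db.shape or da.shape != np.asarray(alt_freqs).shape:
        raise ValueError("dosage and frequency vectors must have equal length")
    terms, _ = _site_lod_terms(da, db, alt_freqs, err)
    return float(terms.sum())


def detect_segments(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    cfg: IBDConfig | None = None,
    alt_freqs: np.ndarray | None = None,
) -> list[IBDSegment]:
    """IBS-exclusion scan for one sample pair.

    Opposite-homozygote sites break candidate runs; runs of jointly-called
    markers must satisfy ``n_markers >= min_markers`` and physical length
    ``>= min_bp``, and score ``lod > 0``.  The reported interval spans the
    first to last supporting marker (half-open).
    """
    cfg = cfg or IBDConfig()
    sample_a, sample_b = pair
    if sample_a == sample_b:
        raise ValueError(f"self-pair {sample_a!r} is not a valid IBD pair")
    samples = matrix.panel.samples
    ia, ib = samples.index(sample_a), samples.index(sample_b)
    if alt_freqs is None:
        alt_freqs = pooled_alt_freqs(matrix)

    da_all = matrix.dosage[:, ia]
    db_all = matrix.dosage[:, ib]
    terms_all, _ = _site_lod_terms(da_all, db_all, alt_freqs, cfg.err)

    segments: list[IBDSegment] = []
    for chrom in matrix.chromosomes:
        m = matrix.chrom_mask(chrom)
        pos = matrix.pos0[m]
        da, db = da_all[m], db_all[m]
        terms = terms_all[m]
        called = np.flatnonzero((da >= 0) & (db >= 0))
        if called.size == 0:
            continue
        opposite = np.abs(da[called].astype(int) - db[called].astype(int)) == 2
        # split the called-marker sequence at opposite-homozygote markers
        for run in _runs_between(called, opposite):
            if run.size < cfg.min_markers:
                continue
            start = int(pos[run[0]])
            end = int(pos[run[-1]]) + 1
            if end - start < cfg.min_bp:
                continue
            lod = float(terms[run].sum())
            if lod <= 0.0:
                continue
            segments.append(
                IBDSegment(
                    sample_a=sample_a,
                    sample_b=sample_b,
                    interval=GenomicInterval(chrom, start, end, score=lod),
                    n_markers=int(run.size),
                    lod=lod,
                )
            )
    return segments


def _runs_between(called: np.ndarray, opposite: np.ndarray):
    """Yield index arrays of called markers between opposite-homozygote breaks."""
    breaks = np.flatnonzero(opposite)
    prev = 0
    for b in breaks:
        if b > prev:
            yield called[prev:b]
        prev = b + 1
    if prev < called.size:
        yield called[prev:]


def detect_all_segments(
    matrix: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    cfg: IBDConfig | None = None,
) -> list[IBDSegment]:
    cfg = cfg or IBDConfig()
    freqs = pooled_alt_freqs(matrix)
    out: list[IBDSegment] = []
    for pair in pairs:
        out.extend(detect_segments(matrix, pair, cfg, alt_freqs=freqs))
    return out


def filter_top_lod(
    segments: Sequence[IBDSegment], keep_quantile: float = 0.5
) -> list[IBDSegment]:
    """Keep segments with LOD at or above the (1 - keep_quantile) quantile.

    With the default 0.5 this keeps the top half by LOD; ties at the
    cutoff are kept.  Empty input yields empty output.
    """
    if not segments:
        return []
    lods = np.array([s.lod for s in segments], dtype=float)
    cutoff = np.quantile(lods, 1.0 - keep_quantile)
    return [s for s in segments if s.lod >= cutoff]


def cross_population_pairs(
    panel: PopulationPanel, pop_x: str, pop_y: str
) -> list[tuple[str, str]]:
    return [
        (a, b)
        for a, b in itertools.product(panel.samples_in(pop_x), panel.samples_in(pop_y))
        if a != b
    ]


def relation_intervals(
    segments: Sequence[IBDSegment],
    pop_x: str,
    pop_y: str,
    panel: PopulationPanel,
    keep_quantile: float = 0.5,
) -> list[GenomicInterval]:
    """Representative IBD intervals of one population relation.

    Restricts to segments whose two samples lie one in each population,
    keeps the top-LOD fraction within that relation set, and union-merges
    the surviving intervals.
    """
    pop = panel.population_of
    related = [
        s
        for s in segments
        if {pop[s.sample_a], pop[s.sample_b]} == {pop_x, pop_y}
    ]
    kept = filter_top_lod(related, keep_quantile)
    return merge_intervals([s.interval for s in kept], book_ended=False)


def transmitted_intervals(
    relations: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Base-pair intersection across the ordered pedigree-relation chain."""
    if len(relations) < 2:
        raise ValueError("transmission needs at least two relation interval sets")
    return intersect_many(list(relations))
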
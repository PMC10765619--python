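"""Windowed population-genetic statistics: nucleotide diversity, Weir &
Cockerham Fst, and the log2 diversity-ratio sweep statistic.

Conventions follow vcftools, which the source pipeline for these scans
typically uses alongside custom scripts:

* per-site diversity is the unbiased heterozygosity ``2 p (1-p) n/(n-1)``
  with ``n`` the number of called alleles at the site;
* windowed diversity divides the sum of site values by the *window length
  in base pairs* (``--window-pi``), not by the number of variant sites;
* windowed Fst is the Weir & Cockerham (1984) "weighted" ratio of sums
  ``sum(a) / sum(a+b+c)`` over sites in the window — never the mean of
  per-site ratios;
* windows tile each chromosome from position 0 with a fixed step, and
  negative windowed Fst values are retained.

The sweep statistic is ``log2(pi_contrast / pi_target)``: large values mean
diversity is depressed in the focal (candidate-swept) population relative
to the contrast, so sweeps in the focal population sit in the upper tail.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_variants",
    "pi_target",
    "pi_ref",
    "fst",
    "log2_ratio",
]


@dataclass
class WindowSpec:
    window_bp: int = 200_000
    step_bp: int = 100_000
    min_variants: int = 10

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must be <= window_bp")
        if self.min_variants < 1:
            raise ValueError("min_variants must be >= 1")

    def starts(self, chrom_len: int) -> np.ndarray:
        return np.arange(0, max(chrom_len, 1), self.step_bp, dtype=np.int64)


def site_pi(alt_count, called_alleles):
    """Unbiased per-site diversity ``2 p (1-p) n/(n-1)``.

    Accepts scalars or arrays.  Sites with fewer than two called alleles
    are excluded (NaN), not an error.
    """
    alt = np.asarray(alt_count, dtype=float)
    n = np.asarray(called_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
        pi = np.where(n >= 2, pi, np.nan)
    if pi.ndim == 0:
        return float(pi)
    return pi


def _pop_site_counts(matrix: GenotypeMatrix, population: str):
    """(alt allele count, called allele count, het count, called diploids)."""
    d = matrix.pop_dosage(population)
    called = d >= 0
    n_dip = called.sum(axis=1)
    alt = np.where(called, d, 0).sum(axis=1)
    het = ((d == 1) & called).sum(axis=1)
    return alt.astype(float), (2 * n_dip).astype(float), het.astype(float), n_dip.astype(float)


def _chrom_lengths(matrix: GenotypeMatrix, chrom_lengths: dict[str, int] | None):
    out = {}
    for chrom in matrix.chromosomes:
        if chrom_lengths and chrom in chrom_lengths:
            out[chrom] = int(chrom_lengths[chrom])
        else:
            out[chrom] = int(matrix.pos0[matrix.chrom_mask(chrom)].max()) + 1
    return out


def _window_sums(pos: np.ndarray, values: np.ndarray, starts: np.ndarray, window_bp: int):
    """Sum ``values`` (NaN ignored) over each window; also count non-NaN sites."""
    vals = np.nan_to_num(values, nan=0.0)
    counts = (~np.isnan(values)).astype(np.int64)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccount = np.concatenate([[0], np.cumsum(counts)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window_bp, side="left")
    return csum[hi] - csum[lo], ccount[hi] - ccount[lo]


def window_pi(
    matrix: GenotypeMatrix,
    population: str,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window diversity of one population (per bp of window length)."""
    spec = spec or WindowSpec()
    alt, n_alleles, _, _ = _pop_site_counts(matrix, population)
    pi = site_pi(alt, n_alleles)
    rows = []
    for chrom, clen in _chrom_lengths(matrix, chrom_lengths).items():
        m = matrix.chrom_mask(chrom)
        pos = matrix.pos0[m]
        starts = spec.starts(clen)
        sums, counts = _window_sums(pos, pi[m], starts, spec.window_bp)
        for s, total, k in zip(starts, sums, counts):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s) + spec.window_bp,
                    "n_variants": int(k),
                    "pi": total / spec.window_bp,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variants", "pi"])


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) Fst, two populations


def _wc_components_arrays(alt1, n1_dip, het1, alt2, n2_dip, het2):
    """Vectorized WC-84 variance components for two populations.

    Inputs are per-site arrays: ALT allele counts, called diploid counts and
    heterozygote counts for each population.  Returns ``(a, d, valid)`` with
    ``d = a + b + c``; sites with < 2 called diploids in either population,
    or monomorphic across both, are flagged invalid (components zeroed).
    """
    n1 = np.asarray(n1_dip, dtype=float)
    n2 = np.asarray(n2_dip, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.asarray(alt1, dtype=float) / (2.0 * n1)
        p2 = np.asarray(alt2, dtype=float) / (2.0 * n2)
        h1 = np.asarray(het1, dtype=float) / n1
        h2 = np.asarray(het2, dtype=float) / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    valid = (n1 >= 2) & (n2 >= 2)
    mono = valid & ((pbar <= 0.0) | (pbar >= 1.0))
    valid &= ~mono
    d = np.where(valid, a + b + c, 0.0)
    a = np.where(valid, a, 0.0)
    return a, d, valid


def wc_fst_site(dosage_a: np.ndarray, dosage_b: np.ndarray) -> tuple[float, float]:
    """WC-84 components ``(a, a+b+c)`` for one site from two dosage vectors.

    Raises ``ValueError`` with fewer than two called diploids in either
    population; returns ``(0.0, 0.0)`` for sites monomorphic across both.
    """
    da = np.asarray(dosage_a)
    db = np.asarray(dosage_b)
    ca, cb = da >= 0, db >= 0
    if ca.sum() < 2 or cb.sum() < 2:
        raise ValueError("need >= 2 called diploids per population")
    a, d, valid = _wc_components_arrays(
        np.array([da[ca].sum()]),
        np.array([ca.sum()]),
        np.array([(da == 1).sum()]),
        np.array([db[cb].sum()]),
        np.array([cb.sum()]),
        np.array([(db == 1).sum()]),
    )
    return float(a[0]), float(d[0])


def window_fst(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed WC-84 Fst (ratio of sums).

    Windows with fewer than ``spec.min_variants`` usable sites, or with a
    zero denominator, are dropped.  Negative estimates are retained.
    """
    spec = spec or WindowSpec()
    table = sweep_table(matrix, pop_a, pop_b, spec, chrom_lengths)
    return table[["chrom", "start", "end", "n_variants", "fst"]].copy()


def sweep_table(
    matrix: GenotypeMatrix,
    target_pop: str,
    ref_pop: str,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Joint window table: diversity of both populations, Fst, log2 ratio.

    One row per window step with at least ``min_variants`` usable Fst sites
    and a positive Fst denominator.  ``log2_ratio = log2(pi_ref/pi_target)``
    is NaN when either windowed diversity is zero; such windows stay in the
    table but are excluded from quantile ranking downstream.
    """
    spec = spec or WindowSpec()
    alt_t, nall_t, het_t, ndip_t = _pop_site_counts(matrix, target_pop)
    alt_r, nall_r, het_r, ndip_r = _pop_site_counts(matrix, ref_pop)
    pi_t = site_pi(alt_t, nall_t)
    pi_r = site_pi(alt_r, nall_r)
    a, d, valid = _wc_components_arrays(alt_t, ndip_t, het_t, alt_r, ndip_r, het_r)

    rows = []
    for chrom, clen in _chrom_lengths(matrix, chrom_lengths).items():
        m = matrix.chrom_mask(chrom)
        pos = matrix.pos0[m]
        starts = spec.starts(clen)
        sum_a, _ = _window_sums(pos, np.where(valid[m], a[m], np.nan), starts, spec.window_bp)
        sum_d, n_sites = _window_sums(
            pos, np.where(valid[m], d[m], np.nan), starts, spec.window_bp
        )
        sum_pit, _ = _window_sums(pos, pi_t[m], starts, spec.window_bp)
        sum_pir, _ = _window_sums(pos, pi_r[m], starts, spec.window_bp)
        for s, sa, sd, k, spt, spr in zip(starts, sum_a, sum_d, n_sites, sum_pit, sum_pir):
            if k < spec.min_variants or sd <= 0.0:
                continue
            pi_target = spt / spec.window_bp
            pi_ref = spr / spec.window_bp
            if pi_target > 0.0 and pi_ref > 0.0:
                log2_ratio = float(np.log2(pi_ref / pi_target))
            else:
                log2_ratio = float("nan")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s) + spec.window_bp,
                    "n_variants": int(k),
                    "pi_target": pi_target,
                    "pi_ref": pi_ref,
                    "fst": sa / sd,
                    "log2_ratio": log2_ratio,
                }
            )
    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    return df.sort_values(["chrom", "start"], ignore_index=True)
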
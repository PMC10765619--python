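"""Population-level SNP/trait association from genotype-count tables.

Works on tables of per-population genotype counts for a biallelic site
(here labelled C/A after the alleles of the intramuscular-fat SNP that
motivated the layout): sample size, trait mean, and counts n_CC, n_CA,
n_AA.  Provides allele frequencies, a Hardy–Weinberg chi-square test, and
ordinary least squares of the trait mean on the A allele frequency.

The HWE chi-square p-value uses df = 2 over the three genotype classes;
monomorphic populations are marked not applicable (they still contribute
to the regression).  Regression frequencies are recomputed exactly from
the counts, not taken from any rounded report column.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeCountRow:
    population: str
    n: int
    n_CC: int
    n_CA: int
    n_AA: int
    trait_mean: float | None = None
    trait_sd: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_CC, self.n_CA, self.n_AA) < 0:
            raise ValueError(f"{self.population}: negative genotype count")
        if self.n_CC + self.n_CA + self.n_AA != self.n:
            raise ValueError(
                f"{self.population}: counts sum to "
                f"{self.n_CC + self.n_CA + self.n_AA}, expected n={self.n}"
            )


@dataclass
class HweResult:
    chi2: float | None
    p: float | None
    df: int
    applicable: bool


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    p_slope: float
    n_points: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def allele_freqs(row: GenotypeCountRow) -> tuple[float, float]:
    """Exact (freq_C, freq_A); they sum to 1 before any rounding."""
    if row.n < 1:
        raise ValueError(f"{row.population}: empty population")
    freq_c = (2 * row.n_CC + row.n_CA) / (2 * row.n)
    return freq_c, 1.0 - freq_c


def hwe_chi2(row: GenotypeCountRow) -> HweResult:
    """Hardy–Weinberg chi-square over the three genotype classes (df = 2).

    Expected counts are n p^2, 2 n p q, n q^2 from the observed allele
    frequencies.  Monomorphic rows are not applicable (the usual table
    prints "-").
    """
    p, q = allele_freqs(row)
    if p == 0.0 or q == 0.0:
        return HweResult(chi2=None, p=None, df=2, applicable=False)
    expected = np.array([row.n * p * p, 2 * row.n * p * q, row.n * q * q])
    observed = np.array([row.n_CC, row.n_CA, row.n_AA], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2=chi2, p=float(stats.chi2.sf(chi2, 2)), df=2, applicable=True)


def fit_freq_trait_regression(rows: Sequence[GenotypeCountRow]) -> RegressionFit:
    """OLS of trait mean (Y) on A allele frequency (X), one point per row.

    Rows without a trait mean are excluded.  R^2 = 1 - SSE/SST and the
    slope p-value is the two-sided t test with n - 2 degrees of freedom.
    """
    pts = [(allele_freqs(r)[1], r.trait_mean) for r in rows if r.trait_mean is not None]
    if len(pts) < 3:
        raise ValueError(f"regression needs >= 3 rows with a trait mean, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all allele frequencies equal")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n_points=len(pts),
    )


def build_table(rows: Sequence[GenotypeCountRow]) -> pd.DataFrame:
    """Per-row derived columns plus a totals row (population = 'Total')."""
    if not rows:
        raise ValueError("build_table needs at least one row")
    out = []
    for r in rows:
        fc, fa = allele_freqs(r)
        hwe = hwe_chi2(r)
        out.append(
            {
                "population": r.population,
                "n": r.n,
                "trait_mean": r.trait_mean,
                "n_CC": r.n_CC,
                "n_CA": r.n_CA,
                "n_AA": r.n_AA,
                "freq_C": round(fc, 3),
                "freq_A": round(fa, 3),
                "hwe_chi2": round(hwe.chi2, 3) if hwe.applicable else None,
                "hwe_p": round(hwe.p, 3) if hwe.applicable else None,
            }
        )
    out.append(
        {
            "population": "Total",
            "n": sum(r.n for r in rows),
            "trait_mean": None,
            "n_CC": sum(r.n_CC for r in rows),
            "n_CA": sum(r.n_CA for r in rows),
            "n_AA": sum(r.n_AA for r in rows),
            "freq_C": None,
            "freq_A": None,
            "hwe_chi2": None,
            "hwe_p": None,
        }
    )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# table I/O

_COLUMNS = ["population", "n", "imf_mean", "imf_sd", "n_CC", "n_CA", "n_AA"]


def read_count_table(path: str | Path) -> list[GenotypeCountRow]:
    """Read a TSV of population genotype counts and trait means.

    Expected columns: population, n, imf_mean, imf_sd (optional/blank),
    n_CC, n_CA, n_AA.  A blank trait mean keeps the row but excludes it
    from regression.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns and c != "imf_sd"]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        mean = getattr(rec, "imf_mean", None)
        sd = getattr(rec, "imf_sd", None)
        rows.append(
            GenotypeCountRow(
                population=str(rec.population),
                n=int(rec.n),
                n_CC=int(rec.n_CC),
                n_CA=int(rec.n_CA),
                n_AA=int(rec.n_AA),
                trait_mean=None if pd.isna(mean) else float(mean),
                trait_sd=None if sd is None or pd.isna(sd) else float(sd),
            )
        )
    return rows


def write_count_table(rows: Sequence[GenotypeCountRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "n": [r.n for r in rows],
            "imf_mean": [r.trait_mean for r in rows],
            "imf_sd": [r.trait_sd for r in rows],
            "n_CC": [r.n_CC for r in rows],
            "n_CA": [r.n_CA for r in rows],
            "n_AA": [r.n_AA for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_reference_table() -> list[GenotypeCountRow]:
    """The packaged 21-population intramuscular-fat genotype-count table."""
    with resources.as_file(
        resources.files("sweepibd").joinpath("data/imf_genotype_counts.tsv")
    ) as path:
        return read_count_table(path)
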
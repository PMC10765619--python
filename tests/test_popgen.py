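"""Diversity and Fst estimators against hand arithmetic and an
independent scalar transcription of the Weir & Cockerham (1984) equations."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepibd.io import PopulationPanel
from sweepibd.popgen import WindowSpec, site_pi, sweep_table, wc_fst_site, window_fst, window_pi
from sweepibd.syndata import SimConfig, simulate_scenario

from conftest import matrix_from_dosage


# ---------------------------------------------------------------------------
# independent oracle: scalar WC-84 transcription (kept loop-by-loop simple)


def wc84_oracle(dos_a, dos_b):
    """Scalar Weir & Cockerham 1984 two-population components (a, a+b+c)."""
    da = [d for d in dos_a if d >= 0]
    db = [d for d in dos_b if d >= 0]
    n1, n2 = len(da), len(db)
    p1 = sum(da) / (2 * n1)
    p2 = sum(db) / (2 * n2)
    h1 = sum(1 for d in da if d == 1) / n1
    h2 = sum(1 for d in db if d == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def windowed_fst_oracle(dosage_a, dosage_b):
    num = den = 0.0
    for site_a, site_b in zip(dosage_a, dosage_b):
        a, d = wc84_oracle(site_a, site_b)
        num += a
        den += d
    return num / den


# ---------------------------------------------------------------------------
# site pi


def test_site_pi_hand_values():
    assert site_pi(2, 4) == pytest.approx(2 * 0.5 * 0.5 * 4 / 3)
    assert site_pi(0, 10) == 0.0
    assert site_pi(10, 10) == 0.0
    assert np.isnan(site_pi(1, 1))  # fewer than two called alleles: excluded


@settings(max_examples=100, derandomize=True)
@given(st.integers(2, 200), st.data())
def test_site_pi_symmetric_in_allele_labels(n, data):
    k = data.draw(st.integers(0, n))
    assert site_pi(k, n) == pytest.approx(site_pi(n - k, n))


def test_window_pi_division_and_conservation(two_pop_panel):
    # one site with pi = 2/3 inside a 1000-bp window
    dosage = np.zeros((1, 8), dtype=np.int8)
    dosage[0, :2] = 1  # popA: alt count 2 of 8 alleles -> p=0.25
    m = matrix_from_dosage(dosage, two_pop_panel, pos0=[100])
    spec = WindowSpec(window_bp=1000, step_bp=1000, min_variants=1)
    table = window_pi(m, "A", spec, chrom_lengths={"1": 1000})
    expected_site = 2 * 0.25 * 0.75 * 8 / 7
    assert table["pi"].iloc[0] == pytest.approx(expected_site / 1000)

    # conservation: non-overlapping windows sum to the chromosome total
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(300, 8)).astype(np.int8)
    pos = np.sort(rng.choice(10_000, 300, replace=False))
    m = matrix_from_dosage(dosage, two_pop_panel, pos0=pos)
    table = window_pi(m, "A", WindowSpec(window_bp=2000, step_bp=2000, min_variants=1),
                      chrom_lengths={"1": 10_000})
    alt = dosage[:, :4]
    pi_sites = site_pi(alt.sum(axis=1), np.full(300, 8))
    assert table["pi"].sum() * 2000 == pytest.approx(np.nansum(pi_sites))


def test_window_with_no_variants_is_zero(two_pop_panel):
    dosage = np.ones((2, 8), dtype=np.int8)
    m = matrix_from_dosage(dosage, two_pop_panel, pos0=[100, 200])
    table = window_pi(m, "A", WindowSpec(window_bp=500, step_bp=500, min_variants=1),
                      chrom_lengths={"1": 2000})
    assert table["pi"].iloc[1] == 0.0
    assert table["n_variants"].iloc[1] == 0


# ---------------------------------------------------------------------------
# Fst


def test_fixed_difference_gives_fst_one():
    a, d = wc_fst_site(np.zeros(10, dtype=np.int8), np.full(10, 2, dtype=np.int8))
    assert a / d == pytest.approx(1.0)


def test_wc_fst_site_matches_oracle_small():
    rng = np.random.default_rng(42)
    for _ in range(50):
        da = rng.integers(0, 3, size=4).astype(np.int8)
        db = rng.integers(0, 3, size=4).astype(np.int8)
        if da.sum() + db.sum() in (0, 16):
            continue  # monomorphic across both: excluded by convention
        a, d = wc_fst_site(da, db)
        oa, od = wc84_oracle(da, db)
        assert a == pytest.approx(oa, abs=1e-12)
        assert d == pytest.approx(od, abs=1e-12)


def test_wc_fst_site_requires_two_called():
    with pytest.raises(ValueError):
        wc_fst_site(np.array([0, -1, -1]), np.array([0, 1, 2]))


def test_windowed_fst_matches_oracle_with_missingness(two_pop_panel):
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.1] = -1
    # guarantee >= 2 called per pop at each site
    dosage[:, :2] = np.abs(dosage[:, :2])
    dosage[:, 4:6] = np.abs(dosage[:, 4:6])
    m = matrix_from_dosage(dosage, two_pop_panel)
    spec = WindowSpec(window_bp=100_000, step_bp=100_000, min_variants=1)
    got = window_fst(m, "A", "B", spec, chrom_lengths={"1": 5000})["fst"].iloc[0]
    want = windowed_fst_oracle(dosage[:, :4], dosage[:, 4:])
    assert got == pytest.approx(want, abs=1e-10)


def test_duplicated_population_fst_near_zero():
    # identical dosage vectors duplicated into both populations
    rng = np.random.default_rng(3)
    half = rng.integers(0, 3, size=(1000, 20)).astype(np.int8)
    dosage = np.concatenate([half, half], axis=1)
    panel = PopulationPanel(
        samples=[f"A_{i}" for i in range(20)] + [f"B_{i}" for i in range(20)],
        population_of={**{f"A_{i}": "A" for i in range(20)},
                       **{f"B_{i}": "B" for i in range(20)}},
    )
    m = matrix_from_dosage(dosage, panel, pos0=np.arange(1000) * 10)
    table = window_fst(m, "A", "B", WindowSpec(window_bp=10_000, step_bp=10_000, min_variants=1),
                       chrom_lengths={"1": 10_000})
    assert abs(table["fst"].iloc[0]) <= 0.05


def test_null_split_population_fst_small():
    """One panmictic population split in two: 95th pct of |windowed Fst| < 0.1."""
    fsts = []
    for seed in range(4):
        cfg = SimConfig(seed=seed, pop_sizes={"A": 20, "B": 20}, pedigree=[],
                        sweep_pop=None, divergence_fst=0.0, n_variants=2000)
        res = simulate_scenario(cfg)
        t = window_fst(res.matrix, "A", "B", WindowSpec(),
                       chrom_lengths={"1": cfg.chrom_bp})
        fsts.extend(abs(t["fst"]))
    assert np.quantile(fsts, 0.95) < 0.1


def test_balding_nichols_recovery():
    """Windowed Fst recovers the divergence parameter 0.2 within +/- 0.03."""
    means = []
    for seed in range(5):
        cfg = SimConfig(seed=seed, pop_sizes={"A": 20, "B": 20}, pedigree=[],
                        sweep_pop=None, divergence_fst=0.2, n_variants=2000)
        res = simulate_scenario(cfg)
        t = window_fst(res.matrix, "A", "B", WindowSpec(),
                       chrom_lengths={"1": cfg.chrom_bp})
        means.append(t["fst"].mean())
    assert np.mean(means) == pytest.approx(0.2, abs=0.03)


# ---------------------------------------------------------------------------
# sweep table


def test_sweep_table_structure_and_ratio(scenario):
    table = sweep_table(scenario.matrix, "S", "Y", WindowSpec(),
                        chrom_lengths={"1": scenario.cfg.chrom_bp})
    assert list(table.columns) == [
        "chrom", "start", "end", "n_variants", "pi_target", "pi_ref", "fst", "log2_ratio"
    ]
    assert (table["start"].diff().dropna() > 0).all()
    # log2 ratio is elevated inside the implanted sweep
    sweep_iv = scenario.truth.sweep_interval
    inside = table[(table["start"] >= sweep_iv.start) & (table["end"] <= sweep_iv.end)]
    outside = table[(table["end"] <= sweep_iv.start) | (table["start"] >= sweep_iv.end)]
    assert inside["log2_ratio"].mean() > outside["log2_ratio"].quantile(0.95)


def test_equal_diversity_gives_zero_ratio(two_pop_panel):
    rng = np.random.default_rng(1)
    half = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
    dosage = np.concatenate([half, half], axis=1)
    m = matrix_from_dosage(dosage, two_pop_panel)
    table = sweep_table(m, "A", "B", WindowSpec(window_bp=10_000, step_bp=10_000, min_variants=1),
                        chrom_lengths={"1": 6000})
    assert table["log2_ratio"].iloc[0] == pytest.approx(0.0)


def test_window_below_min_variants_absent(two_pop_panel):
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
    m = matrix_from_dosage(dosage, two_pop_panel)
    table = sweep_table(m, "A", "B", WindowSpec(window_bp=1000, step_bp=1000, min_variants=10),
                        chrom_lengths={"1": 1000})
    assert table.empty
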
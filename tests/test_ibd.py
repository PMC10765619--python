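"""IBD LOD scoring, segment detection and pedigree transmission."""
import math

import numpy as np
import pytest

from sweepibd.ibd import (
    IBDConfig,
    IBDSegment,
    cross_population_pairs,
    detect_all_segments,
    detect_segments,
    filter_top_lod,
    relation_intervals,
    segment_lod,
    transmitted_intervals,
)
from sweepibd.intervals import GenomicInterval, coverage_fraction
from sweepibd.io import PopulationPanel

from conftest import matrix_from_dosage


def test_segment_lod_closed_forms():
    n = 10
    zeros = np.zeros(n, dtype=np.int8)
    freqs = np.full(n, 0.5)
    # both homozygous reference at p = 0.5: per-site ratio p^3/p^4 = 2
    assert segment_lod(zeros, zeros, freqs) == pytest.approx(10 * math.log10(2))
    # one opposite-homozygote site at p = 0.5, err = 0.001
    da = np.array([2], dtype=np.int8)
    db = np.array([0], dtype=np.int8)
    lod = segment_lod(da, db, np.array([0.5]), err=0.001)
    assert lod == pytest.approx(math.log10(0.001 / 0.0625))
    # all sites missing contribute nothing
    missing = np.full(n, -1, dtype=np.int8)
    assert segment_lod(missing, zeros, freqs) == 0.0
    # frequency outside (0, 1): site skipped
    assert segment_lod(zeros[:1], zeros[:1], np.array([0.0])) == 0.0


def test_segment_lod_symmetric():
    rng = np.random.default_rng(0)
    da = rng.integers(0, 3, 50).astype(np.int8)
    db = rng.integers(0, 3, 50).astype(np.int8)
    q = rng.uniform(0.1, 0.9, 50)
    assert segment_lod(da, db, q) == pytest.approx(segment_lod(db, da, q))


def test_expected_lod_sign_under_ibd_and_independence():
    """Mean per-site LOD is positive for true IBD1 pairs, negative for
    independent pairs (simulation over p ~ Uniform(0.1, 0.9))."""
    rng = np.random.default_rng(42)
    n = 10_000
    q = rng.uniform(0.1, 0.9, n)
    shared = (rng.random(n) < q).astype(np.int8)
    a_other = (rng.random(n) < q).astype(np.int8)
    b_other = (rng.random(n) < q).astype(np.int8)
    ibd_a = shared + a_other
    ibd_b = shared + b_other
    assert segment_lod(ibd_a, ibd_b, q) > 0
    indep_a = ((rng.random(n) < q).astype(np.int8) + (rng.random(n) < q)).astype(np.int8)
    indep_b = ((rng.random(n) < q).astype(np.int8) + (rng.random(n) < q)).astype(np.int8)
    assert segment_lod(indep_a, indep_b, q) < 0


def test_filter_top_lod_median_rule():
    segs = [
        IBDSegment("a", "b", GenomicInterval("1", 0, 10), 5, lod)
        for lod in (1.0, 2.0, 3.0, 4.0)
    ]
    kept = filter_top_lod(segs, 0.5)
    assert sorted(s.lod for s in kept) == [3.0, 4.0]
    assert filter_top_lod(segs[:1], 0.5) == segs[:1]  # single segment kept
    ties = [IBDSegment("a", "b", GenomicInterval("1", 0, 10), 5, 2.0) for _ in range(4)]
    assert len(filter_top_lod(ties, 0.5)) == 4  # ties at the cutoff kept
    assert filter_top_lod([], 0.5) == []


def test_filter_top_lod_halves_except_ties():
    rng = np.random.default_rng(1)
    segs = [
        IBDSegment("a", "b", GenomicInterval("1", 0, 10), 5, float(l))
        for l in rng.normal(size=31)
    ]
    assert len(filter_top_lod(segs, 0.5)) <= (len(segs) + 1) // 2


def test_detect_rejects_self_pair(scenario):
    with pytest.raises(ValueError):
        detect_segments(scenario.matrix, ("S_00", "S_00"))


def test_opposite_homozygotes_break_runs():
    panel = PopulationPanel(samples=["x", "y"], population_of={"x": "P", "y": "P"})
    n = 200
    dosage = np.ones((n, 2), dtype=np.int8)
    dosage[::10, 0] = 0
    dosage[::10, 1] = 2  # opposite homozygotes every 10 markers
    m = matrix_from_dosage(dosage, panel, pos0=np.arange(n) * 1000)
    segs = detect_segments(m, ("x", "y"), IBDConfig(min_markers=50, min_bp=1000))
    assert segs == []


def test_parent_offspring_tract_recovery(scenario):
    """Detected segments cover >= 80% of a recorded parent-offspring tract."""
    pair = scenario.truth.parent_pairs()[0]
    truth = scenario.truth.tracts_between(*pair, "1")
    segs = detect_segments(scenario.matrix, pair)
    cov = coverage_fraction(truth, [s.interval for s in segs])
    assert cov >= 0.8


def test_relation_intervals_exclude_other_relations(scenario):
    panel = scenario.panel
    pairs = cross_population_pairs(panel, "S", "BS")
    segs = detect_all_segments(scenario.matrix, pairs)
    # inject a within-population segment: must not contaminate the relation
    segs.append(IBDSegment("S_00", "S_01", GenomicInterval("2", 0, 10), 99, 1e6))
    merged = relation_intervals(segs, "S", "BS", panel)
    assert all(iv.chrom == "1" for iv in merged)
    truth = [
        GenomicInterval("1", t.start, t.end)
        for t in scenario.truth.ibd_tracts
        if t.kind == "parent"
        and {panel.population_of[t.sample_a], panel.population_of[t.sample_b]}
        == {"S", "BS"}
    ]
    assert coverage_fraction(truth, merged) >= 0.8


def test_transmitted_chain_intersection(scenario):
    m, panel = scenario.matrix, scenario.panel
    sets = []
    for x, y in (("S", "BS"), ("BS", "DBS")):
        segs = detect_all_segments(m, cross_population_pairs(panel, x, y))
        sets.append(relation_intervals(segs, x, y, panel))
    trans = transmitted_intervals(sets)
    assert trans, "no transmitted interval"
    # the implanted region rides along the pedigree chain
    assert coverage_fraction([scenario.truth.sweep_interval], trans) == pytest.approx(1.0)
    # chain of identical sets is the identity
    assert transmitted_intervals([sets[0], sets[0]]) == sets[0]
    # an empty relation empties the chain
    assert transmitted_intervals([sets[0], []]) == []
    with pytest.raises(ValueError):
        transmitted_intervals([sets[0]])
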
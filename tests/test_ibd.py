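import itertools

import numpy as np
import pandas as pd
import pytest

from ibdprio import ibd, pedsim
from ibdprio.genome import demo_genome
from ibdprio.ibd import (DetectorParams, PairError, compute_ibs,
                         degree_from_kinship, detect_pair_segments,
                         detect_segments, pair_sharing, x_male_filter,
                         x_pair_segments)
from ibdprio.matrix import MISSING, GenotypeMatrix
from ibdprio.pedsim import Individual, PedigreeSpec, sib_pair_pedigree


def _matrix_from_calls(a, b, chrom="1", spacing=10_000, sex=("F", "F")):
    n = len(a)
    markers = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, n + 1) * spacing,
        "ref": "A", "alt": "G"})
    calls = np.array([a, b], dtype=np.int8)
    return GenotypeMatrix(["A", "B"], markers, calls,
                          {"A": sex[0], "B": sex[1]})


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

def _ibs_oracle(x, y):
    """Exhaustive genotype-pair table."""
    if x == MISSING or y == MISSING:
        return -1
    if x == y:
        return 2
    if {x, y} == {0, 2}:
        return 0
    return 1


def test_compute_ibs_matches_exhaustive_table():
    states = [0, 1, 2, MISSING]
    pairs = list(itertools.product(states, states))
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    matrix = _matrix_from_calls(a, b)
    got = compute_ibs(matrix, ("A", "B"))
    want = [_ibs_oracle(x, y) for x, y in pairs]
    assert got.tolist() == want


def test_compute_ibs_unknown_sample():
    matrix = _matrix_from_calls([0], [0])
    with pytest.raises(KeyError):
        compute_ibs(matrix, ("A", "Z"))


# ---------------------------------------------------------------------------
# segment detection
# ---------------------------------------------------------------------------

def test_empty_profile_yields_no_segments():
    markers = pd.DataFrame({"chrom": [], "pos": [], "ref": [], "alt": []})
    assert detect_segments(np.array([], dtype=np.int8), markers) == []


def test_monozygotic_duplicate_pair_is_ibd2_everywhere(demo_model):
    spec = PedigreeSpec([
        Individual("FA", "M"), Individual("MO", "F"),
        Individual("T1", "F", "FA", "MO"),
        Individual("T2", "F", "FA", "MO", twin_of="T1"),
    ])
    matrix, _ = pedsim.simulate_pedigree(spec, demo_model, seed=3)
    segs = detect_pair_segments(matrix, ("T1", "T2"))
    auto = [s for s in segs if s.chrom != "X"]
    assert all(s.state == "IBD2" for s in auto)
    # one spanning segment per autosome
    assert len(auto) == len(demo_model.autosomes)
    ps = pair_sharing(segs, demo_model)
    assert ps.p2 > 0.99 and ps.degree == "duplicate"


def test_parent_offspring_ibd1_covers_genome(demo_model):
    matrix, _ = pedsim.simulate_pedigree(sib_pair_pedigree(), demo_model,
                                         seed=17)
    segs = detect_pair_segments(matrix, ("MO", "S1"))
    auto = [s for s in segs if s.chrom != "X"]
    assert all(s.state == "IBD1" for s in auto)
    covered = sum(s.length for s in auto)
    assert covered >= 0.99 * demo_model.autosome_length


def test_unrelated_founders_produce_no_segments():
    model = demo_genome(maf_law=("fixed", 0.3))
    spec = PedigreeSpec([Individual("U1", "F"), Individual("U2", "F")])
    hits = 0
    for seed in range(40):
        matrix, _ = pedsim.simulate_pedigree(spec, model, seed=seed)
        if detect_pair_segments(matrix, ("U1", "U2")):
            hits += 1
    assert hits <= 2  # >= 95% of replicates clean


def test_min_length_monotonicity(sib_sim, demo_model):
    matrix, _ = sib_sim
    totals = []
    for mb in (5, 10, 20, 50):
        params = DetectorParams(min_length_bp=mb * 1_000_000)
        segs = detect_pair_segments(matrix, ("S1", "S2"), params)
        totals.append(sum(s.length for s in segs))
    assert totals == sorted(totals, reverse=True)


def test_segments_within_pair_state_disjoint(sib_sim):
    matrix, _ = sib_sim
    segs = detect_pair_segments(matrix, ("S1", "S2"))
    by_key = {}
    for s in segs:
        assert s.end > s.start
        by_key.setdefault((s.chrom,), []).append((s.start, s.end, s.state))
    for ivals in by_key.values():
        ivals.sort()
        for (s1, e1, _), (s2, e2, _) in zip(ivals[:-1], ivals[1:]):
            assert s2 >= e1  # no overlap even across states


# ---------------------------------------------------------------------------
# sharing statistics
# ---------------------------------------------------------------------------

def test_pair_sharing_no_segments_is_unrelated(demo_model):
    ps = pair_sharing([], demo_model, pair=("A", "B"))
    assert ps.shared == 0 and ps.kinship == 0 and ps.degree == "unrelated"


def test_pair_sharing_arithmetic(demo_model):
    total = demo_model.autosome_length
    segs = [ibd.IBDSegment(("A", "B"), "1", 0, total // 2, "IBD1", 10, 0)]
    ps = pair_sharing(segs, demo_model)
    assert ps.p1 == pytest.approx(0.5)
    assert ps.shared == pytest.approx(0.25)
    assert ps.kinship == pytest.approx(0.125)
    assert ps.degree == "second"


def test_pair_sharing_rejects_unknown_chromosome(demo_model):
    segs = [ibd.IBDSegment(("A", "B"), "chr99", 0, 10, "IBD1", 1, 0)]
    with pytest.raises(ValueError):
        pair_sharing(segs, demo_model)


def test_degree_bins():
    assert degree_from_kinship(0.5) == "duplicate"
    assert degree_from_kinship(0.25) == "first"
    assert degree_from_kinship(0.125) == "second"
    assert degree_from_kinship(0.0625) == "third"
    assert degree_from_kinship(0.01) == "unrelated"


def test_error_robustness_kinship_shift_small(demo_model):
    """0.2% genotyping error moves the sib kinship estimate by < 0.03."""
    diffs = []
    for seed in range(5):
        clean, _ = pedsim.simulate_pedigree(sib_pair_pedigree(), demo_model,
                                            seed=seed)
        noisy, _ = pedsim.simulate_pedigree(sib_pair_pedigree(), demo_model,
                                            error_rate=0.002, seed=seed)
        k0 = pair_sharing(detect_pair_segments(clean, ("S1", "S2")),
                          demo_model).kinship
        k1 = pair_sharing(detect_pair_segments(noisy, ("S1", "S2")),
                          demo_model).kinship
        diffs.append(abs(k1 - k0))
    assert np.mean(diffs) < 0.03


# ---------------------------------------------------------------------------
# X chromosome
# ---------------------------------------------------------------------------

def _x_matrix(a_calls, b_calls, het_marker=None):
    n = len(a_calls)
    markers = pd.DataFrame({
        "chrom": "X", "pos": np.arange(1, n + 1) * 10_000,
        "ref": "A", "alt": "G"})
    calls = np.array([a_calls, b_calls], dtype=np.int8)
    return GenotypeMatrix(["A", "B"], markers, calls, {"A": "M", "B": "M"})


def test_x_male_filter_removes_het_markers():
    m = _x_matrix([0, 1, 2, 0], [0, 0, 2, 2])
    out = x_male_filter(m, ["A", "B"])
    assert out.n_markers == 3
    assert 1 not in out.calls


def test_x_male_filter_identity_when_clean():
    m = _x_matrix([0, 2, 0], [2, 2, 0])
    out = x_male_filter(m, ["A", "B"])
    assert out.equals(m)


def test_x_male_filter_rejects_females():
    m = _x_matrix([0], [0])
    m.sex["B"] = "F"
    with pytest.raises(PairError):
        x_male_filter(m, ["A", "B"])
    with pytest.raises(PairError):
        x_male_filter(m, [])


def test_x_all_het_yields_zero_segments():
    m = _x_matrix([1] * 500, [1] * 500)
    out = x_male_filter(m, ["A", "B"])
    rep = x_pair_segments(out, ("A", "B"))
    assert out.n_markers == 0
    assert rep.longest_bp == 0 and not rep.passes_threshold


def test_identical_x_haplotypes_span_chromosome():
    n = 2000
    calls = list(np.random.default_rng(0).choice([0, 2], size=n))
    m = _x_matrix(calls, list(calls))
    rep = x_pair_segments(m, ("A", "B"), threshold_bp=10_000_000)
    assert rep.passes_threshold
    assert rep.longest_bp >= (n - 1) * 10_000 - 10_000


def test_x_pair_rejects_female():
    m = _x_matrix([0], [0])
    m.sex["A"] = "F"
    with pytest.raises(PairError):
        x_pair_segments(m, ("A", "B"))


def test_unrelated_male_x_rarely_flags():
    model = demo_genome(n_autosomes=1, autosome_mb=10,
                        maf_law=("uniform", 0.1, 0.5))
    spec = PedigreeSpec([Individual("U1", "M"), Individual("U2", "M")])
    flags = 0
    for seed in range(40):
        matrix, _ = pedsim.simulate_pedigree(spec, model, seed=seed)
        filt = x_male_filter(matrix, ["U1", "U2"])
        if x_pair_segments(filt, ("U1", "U2")).passes_threshold:
            flags += 1
    assert flags <= 2


def test_maternal_cousin_x_segment_recovered(demo_model):
    """When male maternal cousins truly share a long X segment, the detector
    recovers a segment overlapping >= 90% of it."""
    spec = pedsim.first_cousin_pedigree(cousin_sexes=("M", "M"),
                                        through="mothers")
    checked = 0
    for seed in range(12):
        matrix, truth = pedsim.simulate_pedigree(spec, demo_model, seed=seed)
        tx = truth.pair_segments("C1", "C2", "X")
        longest = max(((s, e) for s, e, _ in tx), default=None,
                      key=lambda t: t[1] - t[0])
        if longest is None or longest[1] - longest[0] < 10_000_000:
            continue
        checked += 1
        filt = x_male_filter(matrix, ["C1", "C2"])
        rep = x_pair_segments(filt, ("C1", "C2"))
        ts, te = longest
        best = max((min(te, e) - max(ts, s) for s, e in rep.segments),
                   default=0)
        assert best >= 0.9 * (te - ts)
    assert checked >= 3
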
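import itertools

import numpy as np
import pytest

from ibdprio import pedsim
from ibdprio.genome import build_markers, demo_genome
from ibdprio.matrix import MISSING, read_vcf
from ibdprio.pedsim import (Individual, InjectionError, PedigreeError,
                            PedigreeSpec, canonical_two_family_pedigree,
                            drop_haplotypes, first_cousin_pedigree,
                            inject_candidate_variant, meiosis,
                            sib_pair_pedigree, simulate_founders,
                            simulate_pedigree, truth_fraction_shared_by_all,
                            write_outputs)


# ---------------------------------------------------------------------------
# pedigree validation
# ---------------------------------------------------------------------------

def test_pedigree_validation_errors():
    with pytest.raises(PedigreeError):  # duplicate ids
        PedigreeSpec([Individual("A", "M"), Individual("A", "F")])
    with pytest.raises(PedigreeError):  # one parent only
        PedigreeSpec([Individual("A", "M"),
                      Individual("B", "F", father="A", mother=None)])
    with pytest.raises(PedigreeError):  # father is female
        PedigreeSpec([Individual("A", "F"), Individual("B", "F"),
                      Individual("C", "M", father="A", mother="B")])
    with pytest.raises(PedigreeError):  # cycle
        PedigreeSpec([Individual("A", "M", father="B", mother="C"),
                      Individual("B", "M", father="A", mother="C"),
                      Individual("C", "F")])


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def test_founders_zero_maf_all_reference():
    model = demo_genome(n_autosomes=1, autosome_mb=5, x_mb=0,
                        maf_law=("fixed", 0.0))
    _, alleles = simulate_founders(model, 2, seed=0)
    for per_chrom in alleles.values():
        for arr in per_chrom.values():
            assert not arr.any()


def test_founders_deterministic_given_seed():
    model = demo_genome(n_autosomes=2, autosome_mb=10, x_mb=10)
    _, a = simulate_founders(model, 3, seed=9, sexes=["M", "F", "F"])
    _, b = simulate_founders(model, 3, seed=9, sexes=["M", "F", "F"])
    for fid in a:
        for chrom in a[fid]:
            assert np.array_equal(a[fid][chrom], b[fid][chrom])
    # male founders carry a single X haplotype
    assert a["F1"]["X"].shape[0] == 1
    assert a["F2"]["X"].shape[0] == 2


def test_founder_allele_fraction_binomial():
    # 10,000 markers at MAF 0.5: alt fraction within 3 binomial SD
    model = demo_genome(n_autosomes=1, autosome_mb=100, x_mb=0,
                        markers_per_mb=100, maf_law=("fixed", 0.5))
    _, alleles = simulate_founders(model, 1, seed=3)
    hap = alleles["F1"]["1"]
    n = hap.size
    assert n >= 10_000
    se = 3 * np.sqrt(0.25 / n)
    assert abs(hap.mean() - 0.5) < se


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def test_meiosis_zero_rate_returns_one_parental_haplotype(rng):
    parent = [[(0, 10_000_000, ("F", 0))], [(0, 10_000_000, ("F", 1))]]
    gamete, xos = meiosis(parent, 10_000_000, 0.0, rng)
    assert xos == []
    assert gamete in (parent[0], parent[1])


def test_meiosis_crossover_count_poisson_mean():
    # 100 Mb at 1 cM/Mb -> 1 Morgan -> mean 1 crossover
    rng = np.random.default_rng(11)
    parent = [[(0, 100_000_000, ("F", 0))], [(0, 100_000_000, ("F", 1))]]
    counts = [len(meiosis(parent, 100_000_000, 1.0, rng)[1])
              for _ in range(10_000)]
    se = 3 * np.sqrt(1.0 / len(counts))
    assert abs(np.mean(counts) - 1.0) < se


def test_meiosis_requires_two_haplotypes(rng):
    with pytest.raises(PedigreeError):
        meiosis([[(0, 100, ("F", 0))]], 100, 1.0, rng)


def test_gamete_tiles_chromosome(rng):
    parent = [[(0, 50_000_000, ("F", 0))], [(0, 50_000_000, ("F", 1))]]
    for _ in range(20):
        gamete, _ = meiosis(parent, 50_000_000, 2.0, rng)
        assert gamete[0][0] == 0 and gamete[-1][1] == 50_000_000
        for (s1, e1, _l1), (s2, e2, _l2) in zip(gamete[:-1], gamete[1:]):
            assert e1 == s2


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _mendelian_ok(child, father, mother):
    """Allowed child dose given parental doses at an autosomal marker."""
    def gametes(d):
        return {0: {0}, 1: {0, 1}, 2: {1}}[d]
    return child in {f + m for f in gametes(father) for m in gametes(mother)}


def test_trio_mendelian_consistency_error_free(small_model):
    spec = sib_pair_pedigree()
    matrix, _ = simulate_pedigree(spec, small_model, seed=4)
    auto = ~matrix.is_x()
    fa = matrix.calls_for("FA")[auto]
    mo = matrix.calls_for("MO")[auto]
    for child in ("S1", "S2"):
        ch = matrix.calls_for(child)[auto]
        assert all(_mendelian_ok(int(c), int(f), int(m))
                   for c, f, m in zip(ch, fa, mo))


def test_monozygotic_twins_have_identical_genotypes(small_model):
    spec = PedigreeSpec([
        Individual("FA", "M"), Individual("MO", "F"),
        Individual("T1", "M", "FA", "MO"),
        Individual("T2", "M", "FA", "MO", twin_of="T1"),
    ])
    matrix, _ = simulate_pedigree(spec, small_model, seed=5)
    assert np.array_equal(matrix.calls_for("T1"), matrix.calls_for("T2"))


def test_error_rate_one_flips_every_call(small_model):
    spec = sib_pair_pedigree()
    clean, _ = simulate_pedigree(spec, small_model, seed=6)
    noisy, _ = simulate_pedigree(spec, small_model, error_rate=1.0, seed=6)
    assert not (clean.calls == noisy.calls).any()


def test_missing_rate_one_blanks_everything(small_model):
    noisy, _ = simulate_pedigree(sib_pair_pedigree(), small_model,
                                 missing_rate=1.0, seed=6)
    assert (noisy.calls == MISSING).all()


def test_male_x_is_hemizygous_without_error(small_model):
    spec = canonical_two_family_pedigree()
    matrix, truth = simulate_pedigree(spec, small_model, seed=8)
    xmask = matrix.is_x()
    for iid in ("II", "III", "IV"):
        assert len(truth.tracks[iid]["X"]) == 1
        calls = matrix.calls_for(iid)[xmask]
        assert set(np.unique(calls)) <= {0, 2}
    assert len(truth.tracks["I"]["X"]) == 2


# ---------------------------------------------------------------------------
# truth kinship against the recursive pedigree oracle
# ---------------------------------------------------------------------------

def _oracle_kinship(spec, a, b, _memo=None):
    """Independent recursive kinship coefficient on the pedigree graph."""
    if _memo is None:
        _memo = {}
    depth = {}
    for ind in spec.order:
        depth[ind.iid] = 0 if ind.is_founder else 1 + max(
            depth[ind.father], depth[ind.mother])

    def phi(x, y):
        key = tuple(sorted((x, y)))
        if key in _memo:
            return _memo[key]
        ix, iy = spec.by_id[x], spec.by_id[y]
        if x == y:
            val = 0.5 * (1 + (phi(ix.father, ix.mother)
                              if not ix.is_founder else 0.0))
        else:
            if depth[x] < depth[y]:
                x, y, ix, iy = y, x, iy, ix
            if ix.is_founder:
                val = 0.0
            else:
                val = 0.5 * (phi(ix.father, y) + phi(ix.mother, y))
        _memo[key] = val
        return val

    return phi(a, b)


def _truth_kinship(truth, a, b):
    model = truth.model
    bp = {1: 0, 2: 0}
    for chrom in model.autosomes:
        for s, e, state in truth.pair_segments(a, b, chrom.name):
            bp[state] += e - s
    total = model.autosome_length
    return bp[1] / total / 4 + bp[2] / total / 2


@pytest.mark.parametrize("spec_fn,pair,expected", [
    (sib_pair_pedigree, ("S1", "S2"), 0.25),
    (first_cousin_pedigree, ("C1", "C2"), 0.0625),
])
def test_truth_kinship_matches_recursive_oracle(demo_model, spec_fn, pair,
                                                expected):
    spec = spec_fn()
    assert _oracle_kinship(spec, *pair) == pytest.approx(expected)
    rng = np.random.default_rng(100)
    vals = []
    for _ in range(120):
        truth = drop_haplotypes(spec, demo_model, rng)
        vals.append(_truth_kinship(truth, *pair))
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - expected) < 3 * se + 1e-9


def test_cross_family_pairs_are_first_cousins():
    spec = canonical_two_family_pedigree()
    for a, b in itertools.product(("I", "II"), ("III", "IV")):
        assert _oracle_kinship(spec, a, b) == pytest.approx(1 / 16)
    assert _oracle_kinship(spec, "I", "II") == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# shared-by-all fraction
# ---------------------------------------------------------------------------

def test_fraction_shared_trivial_cases(demo_model):
    rng = np.random.default_rng(2)
    spec = PedigreeSpec([Individual("U1", "F"), Individual("U2", "F")])
    truth = drop_haplotypes(spec, demo_model, rng)
    assert truth_fraction_shared_by_all(truth, ["U1", "U1"]) == 1.0
    assert truth_fraction_shared_by_all(truth, ["U1", "U2"]) == 0.0
    with pytest.raises(ValueError):
        truth_fraction_shared_by_all(truth, ["U1"])
    with pytest.raises(KeyError):
        truth_fraction_shared_by_all(truth, ["U1", "NOPE"])


# ---------------------------------------------------------------------------
# variant injection
# ---------------------------------------------------------------------------

def test_inject_variant_carrier_sets(family_sim):
    spec, matrix, truth = family_sim
    probands = list(pedsim.PROBANDS)
    shared = truth.shared_by_all_intervals(probands)
    chrom, s, e = next((c, s, e) for c, iv in shared.items() for s, e in iv)
    pos = (s + e) // 2
    label = sorted(truth.common_label_at(probands, chrom, pos))[0]
    new, carriers, ann = inject_candidate_variant(
        matrix, truth, label, chrom, pos + 1, "C", "T",
        {"gene": "CAND1"})
    assert set(carriers) >= set(probands)
    assert new.n_markers == matrix.n_markers + 1
    j = new.markers.index[(new.markers["chrom"] == chrom)
                          & (new.markers["pos"] == pos + 1)][0]
    for iid in probands:
        assert new.calls[new.sample_index(iid), j] in (1, 2)
    assert ann["gene"] == "CAND1"
    # positions stay sorted within the chromosome
    sel = new.markers["chrom"] == chrom
    assert new.markers.loc[sel, "pos"].is_monotonic_increasing


def test_inject_variant_absent_label_errors(family_sim):
    _, matrix, truth = family_sim
    with pytest.raises(InjectionError):
        inject_candidate_variant(matrix, truth, ("NOBODY", 0), "1", 500_007)


def test_inject_variant_singleton_carrier(family_sim):
    spec, matrix, truth = family_sim
    # a label carried by exactly one proband at some site
    for chrom in ("1", "2", "3"):
        tracks = truth.tracks["I"][chrom]
        s, e, label = tracks[0][0]
        pos = (s + e) // 2
        others = [p for p in pedsim.PROBANDS if p != "I"]
        if not truth.common_label_at(["I", *others], chrom, pos):
            carried_by = [
                p for p in pedsim.PROBANDS
                if label in {lab for tr in truth.tracks[p][chrom]
                             for s2, e2, lab in tr if s2 <= pos < e2}]
            if carried_by == ["I"]:
                _, carriers, _ = inject_candidate_variant(
                    matrix, truth, label, chrom, pos + 1)
                # matrix also holds parents; among probands only I carries it
                assert set(carriers) & set(pedsim.PROBANDS) == {"I"}
                return
    pytest.skip("no singleton label found in this replicate")


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

def test_write_outputs_round_trip(tmp_path, small_model):
    spec = canonical_two_family_pedigree()
    matrix, truth = simulate_pedigree(spec, small_model, seed=13,
                                      missing_rate=0.01)
    paths = write_outputs(matrix, spec, truth, tmp_path)
    back = read_vcf(paths["vcf"], sex=matrix.sex)
    assert back.equals(matrix)
    # truth BED conserves the interval count
    n_lines = sum(1 for _ in open(paths["truth_bed"]))
    assert n_lines == truth.n_intervals
    # PED carries sexes and affection
    from ibdprio.matrix import read_ped
    ped = read_ped(paths["ped"])
    assert list(ped["iid"]) == [i.iid for i in spec.individuals]
    assert ped.set_index("iid")["sex"].to_dict() == {
        i.iid: i.sex for i in spec.individuals}


def test_vcf_bytes_deterministic(tmp_path, small_model):
    spec = sib_pair_pedigree()
    for run in ("a", "b"):
        matrix, truth = simulate_pedigree(spec, small_model, seed=21)
        write_outputs(matrix, spec, truth, tmp_path, prefix=run)
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()
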
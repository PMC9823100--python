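"""Gene-drop pedigree simulation with recombination and true-IBD tracking.

Founder chromosomes are labelled haplotypes; each meiosis draws a Poisson
number of crossovers (rate = genetic length in Morgans under the uniform map)
at uniform physical positions and splices the two parental haplotype tracks.
The resulting piecewise-constant founder-label maps (:class:`TruthIBD`) are
the ground truth against which the IBD detector is validated, and genotypes
are read off the founder alleles along each transmitted track.

Male X chromosomes are hemizygous: a male carries a single, maternally
inherited X haplotype, and his X genotype calls use the homozygous diploid
codes (see :mod:`ibdprio.matrix`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, MarkerSet, build_markers
from .matrix import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING,
                     write_ped, write_vcf)

# A haplotype track: sorted disjoint (start, end, (founder_id, hap_index))
# tuples tiling [0, chromosome length) in 0-based half-open bp coordinates.
Label = tuple[str, int]
Track = list[tuple[int, int, Label]]


class PedigreeError(ValueError):
    pass


class InjectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pedigree specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    iid: str
    sex: str                      # 'M' or 'F'
    father: str | None = None
    mother: str | None = None
    affected: bool = False
    twin_of: str | None = None    # monozygotic twin: clone that sib's gametes

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class PedigreeSpec:
    """Validated pedigree: acyclic, sexes consistent, ids unique."""

    def __init__(self, individuals: list[Individual]):
        self.individuals = list(individuals)
        self.by_id = {ind.iid: ind for ind in individuals}
        if len(self.by_id) != len(individuals):
            raise PedigreeError("duplicate individual ids")
        for ind in individuals:
            if ind.sex not in ("M", "F"):
                raise PedigreeError(f"{ind.iid}: sex must be 'M' or 'F'")
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"{ind.iid}: needs both parents or neither")
            if ind.father is not None:
                for pid, want in ((ind.father, "M"), (ind.mother, "F")):
                    parent = self.by_id.get(pid)
                    if parent is None:
                        raise PedigreeError(f"{ind.iid}: unknown parent {pid!r}")
                    if parent.sex != want:
                        raise PedigreeError(
                            f"{ind.iid}: parent {pid} has sex {parent.sex}, "
                            f"expected {want}")
            if ind.twin_of is not None:
                twin = self.by_id.get(ind.twin_of)
                if twin is None or ind.is_founder or \
                        (twin.father, twin.mother) != (ind.father, ind.mother):
                    raise PedigreeError(
                        f"{ind.iid}: twin_of must name a full sib")
        self.order = self._topological_order()

    def _topological_order(self) -> list[Individual]:
        done: dict[str, Individual] = {}
        pending = list(self.individuals)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                deps = [p for p in (ind.father, ind.mother, ind.twin_of) if p]
                if all(d in done for d in deps):
                    done[ind.iid] = ind
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:
                raise PedigreeError("pedigree contains a cycle")
            pending = remaining
        return list(done.values())

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    def sex_of(self, iid: str) -> str:
        return self.by_id[iid].sex

    def ped_rows(self):
        for ind in self.individuals:
            yield ind.iid, ind.sex, ind.father, ind.mother, ind.affected


def canonical_two_family_pedigree() -> PedigreeSpec:
    """Two affected sib-pairs whose mothers are full sisters.

    The four probands I-IV (I female; II, III, IV male) are the genotyped
    individuals; within-family pairs are full sibs and cross-family pairs are
    first cousins (third-degree relatives, kinship 1/16).  The male probands
    II and III carry maternally derived X chromosomes that can trace back to
    the shared maternal grandparents.
    """
    return PedigreeSpec([
        Individual("GF", "M"), Individual("GM", "F"),
        Individual("F1", "M"), Individual("F2", "M"),
        Individual("M1", "F", "GF", "GM", affected=True),
        Individual("M2", "F", "GF", "GM", affected=True),
        Individual("I", "F", "F1", "M1", affected=True),
        Individual("II", "M", "F1", "M1", affected=True),
        Individual("III", "M", "F2", "M2", affected=True),
        Individual("IV", "M", "F2", "M2", affected=True),
    ])


PROBANDS = ("I", "II", "III", "IV")


def sib_pair_pedigree() -> PedigreeSpec:
    return PedigreeSpec([
        Individual("FA", "M"), Individual("MO", "F"),
        Individual("S1", "F", "FA", "MO"), Individual("S2", "M", "FA", "MO"),
    ])


def first_cousin_pedigree(cousin_sexes: tuple[str, str] = ("F", "M"),
                          through: str = "mothers") -> PedigreeSpec:
    """Two first cousins linked through sibling parents.

    ``through='mothers'`` makes the linking sibs sisters, so male cousins are
    maternal cousins sharing X ancestry through the grandparents.
    """
    link_sex = "F" if through == "mothers" else "M"
    spouse_sex = "M" if link_sex == "F" else "F"
    inds = [Individual("GF", "M"), Individual("GM", "F"),
            Individual("L1", link_sex, "GF", "GM"),
            Individual("L2", link_sex, "GF", "GM"),
            Individual("SP1", spouse_sex), Individual("SP2", spouse_sex)]
    for k, csex in enumerate(cousin_sexes, start=1):
        link, sp = f"L{k}", f"SP{k}"
        father, mother = (sp, link) if link_sex == "F" else (link, sp)
        inds.append(Individual(f"C{k}", csex, father, mother))
    return PedigreeSpec(inds)


# ---------------------------------------------------------------------------
# Founder haplotypes
# ---------------------------------------------------------------------------

def founder_alleles(markers: MarkerSet, founders: list[tuple[str, str]],
                    rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Draw founder haplotype alleles: Bernoulli(MAF) per marker per haplotype.

    Returns founder id -> chromosome -> (n_haplotypes, n_markers) uint8 array.
    Males carry a single X haplotype.
    """
    model = markers.model
    out: dict[str, dict[str, np.ndarray]] = {}
    for fid, sex in founders:
        per_chrom = {}
        for chrom in model.chromosomes:
            n_h = 1 if (chrom.is_x and sex == "M") else 2
            maf = markers.mafs[chrom.name]
            per_chrom[chrom.name] = (
                rng.random((n_h, maf.size)) < maf).astype(np.uint8)
        out[fid] = per_chrom
    return out


def simulate_founders(model: GenomeModel, n_founders: int, seed: int,
                      sexes: list[str] | None = None
                      ) -> tuple[MarkerSet, dict[str, dict[str, np.ndarray]]]:
    """Stand-alone founder simulation (markers drawn from the model's MAF law)."""
    if n_founders < 1:
        raise PedigreeError("need at least one founder")
    rng = np.random.default_rng(seed)
    markers = build_markers(model, rng)
    if sexes is None:
        sexes = ["F"] * n_founders
    founders = [(f"F{k + 1}", s) for k, s in zip(range(n_founders), sexes)]
    return markers, founder_alleles(markers, founders, rng)


# ---------------------------------------------------------------------------
# Meiosis and gene drop
# ---------------------------------------------------------------------------

def _clip_track(track: Track, a: int, b: int) -> Track:
    out = []
    for s, e, lab in track:
        s2, e2 = max(s, a), min(e, b)
        if e2 > s2:
            out.append((s2, e2, lab))
    return out


def _merge_adjacent(track: Track) -> Track:
    out: Track = []
    for seg in track:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def meiosis(parent_tracks: list[Track], length_bp: int, morgans: float,
            rng: np.random.Generator) -> tuple[Track, list[int]]:
    """One meiosis: Poisson crossovers at uniform positions, fair-coin start.

    Returns the gamete haplotype track and the crossover positions.
    """
    if len(parent_tracks) != 2:
        raise PedigreeError(
            f"meiosis needs two parental haplotypes, got {len(parent_tracks)}")
    n_xo = rng.poisson(morgans)
    xos = sorted(int(x) for x in rng.uniform(0, length_bp, size=n_xo))
    xos = [x for x in dict.fromkeys(xos) if 0 < x < length_bp]
    cur = int(rng.integers(2))
    gamete: Track = []
    bounds = [0, *xos, length_bp]
    for a, b in zip(bounds[:-1], bounds[1:]):
        gamete.extend(_clip_track(parent_tracks[cur], a, b))
        cur ^= 1
    return _merge_adjacent(gamete), xos


# ---------------------------------------------------------------------------
# TruthIBD
# ---------------------------------------------------------------------------

@dataclass
class TruthIBD:
    """Ground-truth founder-label maps for every individual and haplotype."""

    model: GenomeModel
    tracks: dict[str, dict[str, list[Track]]]  # iid -> chrom -> haplotype tracks

    def _require(self, iid: str) -> dict[str, list[Track]]:
        if iid not in self.tracks:
            raise KeyError(f"unknown sample {iid!r} in truth")
        return self.tracks[iid]

    @staticmethod
    def _labels_at(tracks: list[Track], x: float) -> list[Label]:
        labels = []
        for tr in tracks:
            for s, e, lab in tr:
                if s <= x < e:
                    labels.append(lab)
                    break
        return labels

    def pair_segments(self, a: str, b: str, chrom: str
                      ) -> list[tuple[int, int, int]]:
        """(start, end, ibd_state) intervals for one pair on one chromosome.

        The IBD state at a locus is the multiset intersection size of the two
        individuals' founder-label sets (0, 1 or 2); only state >= 1 intervals
        are returned, adjacent equal-state intervals merged.
        """
        ta, tb = self._require(a)[chrom], self._require(b)[chrom]
        bps = sorted({p for tr in (*ta, *tb) for s, e, _ in tr for p in (s, e)})
        out: list[tuple[int, int, int]] = []
        for s, e in zip(bps[:-1], bps[1:]):
            mid = (s + e) / 2
            la = Counter(self._labels_at(ta, mid))
            lb = Counter(self._labels_at(tb, mid))
            state = sum((la & lb).values())
            if state >= 1:
                if out and out[-1][1] == s and out[-1][2] == state:
                    out[-1] = (out[-1][0], e, state)
                else:
                    out.append((s, e, state))
        return out

    def pair_ibd_intervals(self, a: str, b: str, autosomes_only: bool = True
                           ) -> dict[str, list[tuple[int, int]]]:
        """State-agnostic (IBD >= 1) truth intervals per chromosome."""
        chroms = self.model.autosomes if autosomes_only else self.model.chromosomes
        return {
            c.name: [(s, e) for s, e, _ in self.pair_segments(a, b, c.name)]
            for c in chroms
        }

    def shared_by_all_intervals(self, ids: list[str]
                                ) -> dict[str, list[tuple[int, int]]]:
        """Autosomal intervals where every listed sample carries >= 1 copy of
        a common founder allele, found by a breakpoint sweep."""
        ids = list(dict.fromkeys(ids))
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom in self.model.autosomes:
            per_sample = [self._require(i)[chrom.name] for i in ids]
            bps = sorted({p for tracks in per_sample for tr in tracks
                          for s, e, _ in tr for p in (s, e)})
            ivals: list[tuple[int, int]] = []
            for s, e in zip(bps[:-1], bps[1:]):
                mid = (s + e) / 2
                common = set(self._labels_at(per_sample[0], mid))
                for tracks in per_sample[1:]:
                    common &= set(self._labels_at(tracks, mid))
                    if not common:
                        break
                if common:
                    if ivals and ivals[-1][1] == s:
                        ivals[-1] = (ivals[-1][0], e)
                    else:
                        ivals.append((s, e))
            out[chrom.name] = ivals
        return out

    def fraction_shared_by_all(self, ids: list[str]) -> float:
        shared = self.shared_by_all_intervals(ids)
        total = sum(e - s for ivals in shared.values() for s, e in ivals)
        return total / self.model.autosome_length

    def common_label_at(self, ids: list[str], chrom: str, x: float
                        ) -> set[Label]:
        ids = list(dict.fromkeys(ids))
        common = set(self._labels_at(self._require(ids[0])[chrom], x))
        for i in ids[1:]:
            common &= set(self._labels_at(self._require(i)[chrom], x))
        return common

    def bed_rows(self):
        for iid, per_chrom in self.tracks.items():
            for chrom, tracks in per_chrom.items():
                for h, track in enumerate(tracks):
                    for s, e, (fid, fh) in track:
                        yield chrom, s, e, f"{iid}|{h}|{fid}|{fh}"

    @property
    def n_intervals(self) -> int:
        return sum(1 for _ in self.bed_rows())


def truth_fraction_shared_by_all(truth: TruthIBD, ids: list[str]) -> float:
    """Fraction of the autosomal genome where all listed samples share at
    least one founder allele identical by descent."""
    if len(ids) < 2:
        raise ValueError("need at least two sample ids")
    return truth.fraction_shared_by_all(ids)


# ---------------------------------------------------------------------------
# Gene drop + genotype synthesis
# ---------------------------------------------------------------------------

def drop_haplotypes(spec: PedigreeSpec, model: GenomeModel,
                    rng: np.random.Generator) -> TruthIBD:
    """Transmit labelled founder haplotypes through the pedigree."""
    tracks: dict[str, dict[str, list[Track]]] = {}
    for ind in spec.order:
        per_chrom: dict[str, list[Track]] = {}
        if ind.twin_of is not None:
            tracks[ind.iid] = {
                c: [list(t) for t in hs] for c, hs in tracks[ind.twin_of].items()
            }
            continue
        for chrom in model.chromosomes:
            L, M = chrom.length_bp, model.morgans(chrom)
            if ind.is_founder:
                n_h = 1 if (chrom.is_x and ind.sex == "M") else 2
                per_chrom[chrom.name] = [
                    [(0, L, (ind.iid, h))] for h in range(n_h)]
                continue
            fa, mo = tracks[ind.father], tracks[ind.mother]
            haps: list[Track] = []
            if chrom.is_x:
                if ind.sex == "F":
                    # father's single X passed unrecombined
                    haps.append([tuple(seg) for seg in fa[chrom.name][0]])
                haps.append(meiosis(mo[chrom.name], L, M, rng)[0])
            else:
                haps.append(meiosis(fa[chrom.name], L, M, rng)[0])
                haps.append(meiosis(mo[chrom.name], L, M, rng)[0])
            per_chrom[chrom.name] = haps
        tracks[ind.iid] = per_chrom
    return TruthIBD(model, tracks)


def _track_alleles(track: Track, positions: np.ndarray,
                   alleles: dict[str, np.ndarray], chrom: str) -> np.ndarray:
    out = np.zeros(positions.size, dtype=np.uint8)
    for s, e, (fid, h) in track:
        i0 = np.searchsorted(positions, s + 1, side="left")
        i1 = np.searchsorted(positions, e, side="right")
        out[i0:i1] = alleles[fid][chrom][h, i0:i1]
    return out


def genotypes_from_truth(spec: PedigreeSpec, markers: MarkerSet,
                         truth: TruthIBD,
                         alleles: dict[str, dict[str, np.ndarray]],
                         samples: list[str]) -> GenotypeMatrix:
    model = markers.model
    frames = []
    per_chrom_calls = []
    for chrom in model.chromosomes:
        pos = markers.positions[chrom.name]
        frames.append(pd.DataFrame({
            "chrom": chrom.name, "pos": pos,
            "ref": markers.ref[chrom.name], "alt": markers.alt[chrom.name]}))
        rows = np.empty((len(samples), pos.size), dtype=np.int8)
        for i, iid in enumerate(samples):
            tr = truth.tracks[iid][chrom.name]
            dose = sum(_track_alleles(t, pos, alleles, chrom.name) for t in tr)
            if len(tr) == 1:  # hemizygous male X -> homozygous encoding
                dose = dose * 2
            rows[i] = dose
        per_chrom_calls.append(rows)
    markers_df = pd.concat(frames, ignore_index=True)
    calls = np.concatenate(per_chrom_calls, axis=1)
    sex = {iid: spec.sex_of(iid) for iid in samples}
    return GenotypeMatrix(list(samples), markers_df, calls, sex)


def apply_noise(matrix: GenotypeMatrix, error_rate: float, missing_rate: float,
                rng: np.random.Generator) -> GenotypeMatrix:
    """Symmetric state-flip errors, then missingness, applied in place.

    Each call is flipped to one of the other valid states with probability
    ``error_rate`` (male X calls flip between the two hemizygous states), then
    independently set missing with probability ``missing_rate``.
    """
    for rate, name in ((error_rate, "error_rate"), (missing_rate, "missing_rate")):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    calls = matrix.calls
    xmask = matrix.is_x()
    male = np.array([matrix.sex.get(s) == "M" for s in matrix.samples])
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        flipped = (calls + shift) % 3
        haploid = male[:, None] & xmask[None, :]
        flipped = np.where(haploid, 2 - calls, flipped)  # 0 <-> 2
        calls = np.where(flip, flipped, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate,
                         np.int8(MISSING), calls).astype(np.int8)
    matrix.calls = calls
    return matrix


def simulate_pedigree(spec: PedigreeSpec, model: GenomeModel,
                      error_rate: float = 0.0, missing_rate: float = 0.0,
                      seed: int = 0, samples: list[str] | None = None
                      ) -> tuple[GenotypeMatrix, TruthIBD]:
    """Simulate genotypes for a pedigree and return them with the truth maps.

    ``samples`` restricts the genotype matrix to a subset of individuals
    (e.g. only the sequenced probands); the truth covers everyone.
    """
    rng = np.random.default_rng(seed)
    markers = build_markers(model, rng)
    alleles = founder_alleles(
        markers, [(f.iid, f.sex) for f in spec.founders], rng)
    truth = drop_haplotypes(spec, model, rng)
    if samples is None:
        samples = [ind.iid for ind in spec.individuals]
    matrix = genotypes_from_truth(spec, markers, truth, alleles, samples)
    apply_noise(matrix, error_rate, missing_rate, rng)
    return matrix, truth


# ---------------------------------------------------------------------------
# Candidate-variant injection
# ---------------------------------------------------------------------------

def inject_candidate_variant(matrix: GenotypeMatrix, truth: TruthIBD,
                             label: Label, chrom: str, pos: int,
                             ref: str = "C", alt: str = "T",
                             annotation: dict | None = None
                             ) -> tuple[GenotypeMatrix, list[str], dict]:
    """Add a rare variant carried exactly by samples whose truth haplotypes
    carry ``label`` at the site.

    Returns the new matrix, the carrier ids, and an annotation row suitable
    for the variant-prioritization sidecar table.
    """
    x = pos - 1  # 0-based site
    doses = {}
    for iid in matrix.samples:
        tracks = truth.tracks.get(iid, {}).get(chrom, [])
        doses[iid] = sum(
            1 for tr in tracks for s, e, lab in tr
            if lab == label and s <= x < e)
    if all(d == 0 for d in doses.values()):
        raise InjectionError(
            f"founder label {label} absent at {chrom}:{pos} in all samples")
    col = np.array([min(doses[iid], 2) if doses[iid] else HOM_REF
                    for iid in matrix.samples], dtype=np.int8)
    # hemizygous males: one labelled track = hemizygous alt (homozygous code)
    for i, iid in enumerate(matrix.samples):
        if matrix.sex.get(iid) == "M" and chrom == "X" and doses[iid] == 1:
            col[i] = HOM_ALT
    mk = matrix.markers
    chrom_order = {c: k for k, c in enumerate(dict.fromkeys(mk["chrom"]))}
    key = (chrom_order.get(chrom, len(chrom_order)), pos)
    keys = list(zip(mk["chrom"].map(chrom_order), mk["pos"]))
    insert_at = next((i for i, k in enumerate(keys) if k >= key), len(keys))
    row = pd.DataFrame({"chrom": [chrom], "pos": [pos], "ref": [ref], "alt": [alt]})
    new_markers = pd.concat(
        [mk.iloc[:insert_at], row, mk.iloc[insert_at:]], ignore_index=True)
    new_calls = np.insert(matrix.calls, insert_at, col, axis=1)
    new_matrix = GenotypeMatrix(list(matrix.samples), new_markers, new_calls,
                                dict(matrix.sex))
    carriers = [iid for iid in matrix.samples if doses[iid] > 0]
    ann = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    ann.update(annotation or {})
    return new_matrix, carriers, ann


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_truth_bed(truth: TruthIBD, path) -> int:
    """Write every truth interval as BED4 (name = sample|hap|founder|hap)."""
    n = 0
    with open(path, "w") as fh:
        for chrom, s, e, name in truth.bed_rows():
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
            n += 1
    return n


def write_outputs(matrix: GenotypeMatrix, spec: PedigreeSpec, truth: TruthIBD,
                  outdir, prefix: str = "sim") -> dict[str, Path]:
    """Write VCF + PED + truth BED; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "ped": outdir / f"{prefix}.ped",
        "truth_bed": outdir / f"{prefix}.truth.bed",
    }
    contigs = {c.name: c.length_bp for c in truth.model.chromosomes}
    write_vcf(matrix, paths["vcf"], contig_lengths=contigs)
    write_ped(spec.ped_rows(), paths["ped"])
    write_truth_bed(truth, paths["truth_bed"])
    return paths
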
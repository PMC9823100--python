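"""Pairwise IBD segment detection from unphased genotypes.

The detector works on identity-by-state (IBS) profiles.  For a sample pair,
each marker is IBS2 (identical non-missing calls), IBS0 (opposite
homozygotes) or IBS1 (anything else); markers with a missing call are
unusable and excluded.  Under IBD1 sharing IBS0 is impossible apart from
genotyping error, and under IBD2 every marker is IBS2, so:

* an IBD1 candidate is a maximal run of usable markers in which every sliding
  window of ``window`` markers contains at most ``ibd1_max_ibs0`` IBS0 calls;
* an IBD2 candidate likewise bounds the count of non-IBS2 calls per window.

Candidates are trimmed to the outermost consistent marker, merged across
small gaps, and filtered by physical length and supporting marker count.
Where IBD2 and IBD1 candidates overlap, IBD2 wins and the IBD1 remainder is
re-emitted if it still passes the thresholds.

Genome-wide sharing statistics follow the usual kinship algebra:
``kinship = p1/4 + p2/2`` with relationship degrees called from the standard
powers-of-two kinship bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, is_x_name
from .matrix import GenotypeMatrix, HET, MISSING

IBS_UNUSABLE = -1


class PairError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorParams:
    """Windowed IBS-run detector tolerances.

    window is in usable markers; tolerances are violation counts per window.
    Candidates closer than ``window`` usable markers are merged.
    """

    window: int = 100
    ibd1_max_ibs0: int = 1
    ibd2_max_non_ibs2: int = 5
    min_length_bp: int = 5_000_000
    min_length_bp_x: int = 10_000_000
    min_markers: int = 100


DEFAULT_PARAMS = DetectorParams()


@dataclass(frozen=True)
class IBDSegment:
    pair: tuple[str, str]
    chrom: str
    start: int       # 0-based half-open
    end: int
    state: str       # "IBD1" | "IBD2"
    n_markers: int
    n_violations: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PairSharing:
    """Genome-wide autosomal sharing for one pair."""

    pair: tuple[str, str]
    p1: float        # fraction of autosomes in IBD1 segments
    p2: float        # fraction in IBD2
    shared: float    # expected allele-sharing fraction p1/2 + p2
    kinship: float   # p1/4 + p2/2
    coverage: float  # plain segment coverage p1 + p2
    degree: str


# kinship >= threshold -> degree, standard powers-of-two convention
_DEGREE_BINS = (
    (0.354, "duplicate"),
    (0.177, "first"),
    (0.0884, "second"),
    (0.0442, "third"),
)


def degree_from_kinship(kinship: float) -> str:
    for thr, name in _DEGREE_BINS:
        if kinship >= thr:
            return name
    return "unrelated"


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

def compute_ibs(matrix: GenotypeMatrix, pair: tuple[str, str]) -> np.ndarray:
    """Per-marker IBS states for a pair: 0/1/2, -1 where either call missing."""
    a = matrix.calls_for(pair[0])
    b = matrix.calls_for(pair[1])
    ibs = np.ones(a.shape, dtype=np.int8)
    ibs[a == b] = 2
    ibs[np.abs(a.astype(np.int16) - b) == 2] = 0
    ibs[(a == MISSING) | (b == MISSING)] = IBS_UNUSABLE
    return ibs


# ---------------------------------------------------------------------------
# Windowed run detection
# ---------------------------------------------------------------------------

def _window_runs(viol: np.ndarray, window: int, tol: int) -> list[tuple[int, int]]:
    """Maximal index runs [s, e] (inclusive) covered by passing windows.

    A window of ``window`` consecutive entries passes when it contains at
    most ``tol`` True entries; runs are the union of passing windows, trimmed
    so they do not start or end on a violation, then merged across gaps
    smaller than ``window``.
    """
    n = viol.size
    if n == 0:
        return []
    w = min(window, n)
    counts = np.convolve(viol.astype(np.int32), np.ones(w, dtype=np.int32),
                         mode="valid")
    ok = counts <= tol
    if not ok.any():
        return []
    # union of passing windows via a difference array
    diff = np.zeros(n + 1, dtype=np.int32)
    idx = np.flatnonzero(ok)
    np.add.at(diff, idx, 1)
    np.add.at(diff, idx + w, -1)
    covered = np.cumsum(diff[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    runs = [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]
    trimmed = []
    for s, e in runs:
        while s <= e and viol[s]:
            s += 1
        while e >= s and viol[e]:
            e -= 1
        if e >= s:
            trimmed.append((s, e))
    merged: list[list[int]] = []
    for s, e in trimmed:
        if merged and s - merged[-1][1] - 1 < window:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract_spans(span: tuple[int, int], holes: list[tuple[int, int]]
                    ) -> list[tuple[int, int]]:
    """Subtract bp intervals ``holes`` from bp interval ``span``."""
    out = []
    cur = span[0]
    for hs, he in sorted(holes):
        if he <= span[0] or hs >= span[1]:
            continue
        if hs > cur:
            out.append((cur, min(hs, span[1])))
        cur = max(cur, he)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


def detect_segments(profile: np.ndarray, markers: pd.DataFrame,
                    params: DetectorParams = DEFAULT_PARAMS,
                    pair: tuple[str, str] = ("A", "B")) -> list[IBDSegment]:
    """Detect IBD1/IBD2 segments from an IBS profile.

    ``profile`` and ``markers`` (chrom/pos columns) must be index-aligned.
    Returns merged, non-overlapping segments; IBD2 takes precedence over
    overlapping IBD1, whose remainder is re-emitted if it still passes the
    length and marker-count thresholds.
    """
    if profile.size == 0:
        return []
    segments: list[IBDSegment] = []
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy(dtype=np.int64)
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        ibs = profile[sel]
        pos = pos_arr[sel]
        usable = ibs != IBS_UNUSABLE
        ibs_u, pos_u = ibs[usable], pos[usable]
        if ibs_u.size == 0:
            continue
        min_len = (params.min_length_bp_x if is_x_name(chrom)
                   else params.min_length_bp)

        def _emit(runs, state, viol):
            out = []
            for s, e in runs:
                start, end = int(pos_u[s]) - 1, int(pos_u[e])
                n_mark = e - s + 1
                if end - start >= min_len and n_mark >= params.min_markers:
                    out.append(IBDSegment(
                        pair, chrom, start, end, state, n_mark,
                        int(viol[s:e + 1].sum())))
            return out

        viol2 = ibs_u != 2
        runs2 = _window_runs(viol2, params.window, params.ibd2_max_non_ibs2)
        ibd2 = _emit(runs2, "IBD2", viol2)
        segments.extend(ibd2)

        viol1 = ibs_u == 0
        runs1 = _window_runs(viol1, params.window, params.ibd1_max_ibs0)
        holes = [(g.start, g.end) for g in ibd2]
        for s, e in runs1:
            span = (int(pos_u[s]) - 1, int(pos_u[e]))
            for fs, fe in _subtract_spans(span, holes):
                i0 = int(np.searchsorted(pos_u, fs + 1, side="left"))
                i1 = int(np.searchsorted(pos_u, fe, side="right"))
                n_mark = i1 - i0
                if fe - fs >= min_len and n_mark >= params.min_markers:
                    segments.append(IBDSegment(
                        pair, chrom, fs, fe, "IBD1", n_mark,
                        int(viol1[i0:i1].sum())))
    return segments


def detect_pair_segments(matrix: GenotypeMatrix, pair: tuple[str, str],
                         params: DetectorParams = DEFAULT_PARAMS
                         ) -> list[IBDSegment]:
    """Convenience wrapper: IBS profile + detection for one pair."""
    return detect_segments(compute_ibs(matrix, pair), matrix.markers,
                           params, pair)


# ---------------------------------------------------------------------------
# Sharing statistics
# ---------------------------------------------------------------------------

def pair_sharing(segments: list[IBDSegment], model: GenomeModel,
                 pair: tuple[str, str] | None = None) -> PairSharing:
    """Genome-wide autosomal IBD1/IBD2 fractions, kinship and degree call."""
    auto_names = {c.name for c in model.autosomes}
    known = {c.name for c in model.chromosomes}
    bp = {"IBD1": 0, "IBD2": 0}
    for seg in segments:
        if seg.chrom not in known:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        if seg.chrom in auto_names:
            bp[seg.state] += seg.length
        if pair is None:
            pair = seg.pair
    total = model.autosome_length
    p1, p2 = bp["IBD1"] / total, bp["IBD2"] / total
    kinship = p1 / 4 + p2 / 2
    return PairSharing(
        pair=pair or ("A", "B"), p1=p1, p2=p2,
        shared=p1 / 2 + p2, kinship=kinship, coverage=p1 + p2,
        degree=degree_from_kinship(kinship),
    )


def analyze_pairs(matrix: GenotypeMatrix, model: GenomeModel,
                  params: DetectorParams = DEFAULT_PARAMS,
                  samples: list[str] | None = None
                  ) -> dict[tuple[str, str], tuple[list[IBDSegment], PairSharing]]:
    """Detect segments and sharing statistics for every unordered pair."""
    samples = samples or matrix.samples
    out = {}
    for pair in itertools.combinations(samples, 2):
        segs = detect_pair_segments(matrix, pair, params)
        out[pair] = (segs, pair_sharing(segs, model, pair))
    return out


def sharing_table(results) -> pd.DataFrame:
    rows = []
    for pair, (_, ps) in results.items():
        rows.append({
            "sample1": pair[0], "sample2": pair[1],
            "p1": ps.p1, "p2": ps.p2, "shared": ps.shared,
            "coverage": ps.coverage, "kinship": ps.kinship,
            "degree": ps.degree,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# X chromosome, male-male analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class XSegmentReport:
    pair: tuple[str, str]
    longest_bp: int
    passes_threshold: bool
    n_markers_used: int
    segments: tuple = ()


def _require_male(matrix: GenotypeMatrix, iid: str) -> None:
    sex = matrix.sex.get(iid)
    if sex != "M":
        raise PairError(f"sample {iid!r} is not male (sex={sex!r})")


def x_male_filter(matrix: GenotypeMatrix, male_ids: list[str]) -> GenotypeMatrix:
    """Drop X markers heterozygous in any listed male.

    A heterozygous male X call is a genotyping artifact (males are
    hemizygous), so such markers are removed jointly for all pairs.
    """
    if not male_ids:
        raise PairError("male id list is empty")
    for iid in male_ids:
        _require_male(matrix, iid)
    xmask = matrix.is_x()
    rows = np.array([matrix.sample_index(i) for i in male_ids])
    het_any = (matrix.calls[rows] == HET).any(axis=0)
    return matrix.subset_markers(~(xmask & het_any))


def x_pair_segments(matrix: GenotypeMatrix, pair: tuple[str, str],
                    threshold_bp: int = 10_000_000,
                    params: DetectorParams = DEFAULT_PARAMS) -> XSegmentReport:
    """Longest shared X segment between two males.

    Hemizygous calls are compared as haploid alleles; a shared segment is a
    maximal run where the windowed allele-mismatch count stays within the
    IBD1 tolerance.  Missing and (artifact) heterozygous calls are excluded.
    """
    for iid in pair:
        _require_male(matrix, iid)
    xmask = matrix.is_x()
    a = matrix.calls_for(pair[0])[xmask]
    b = matrix.calls_for(pair[1])[xmask]
    pos = matrix.markers.loc[xmask, "pos"].to_numpy(dtype=np.int64)
    usable = (a != MISSING) & (b != MISSING) & (a != HET) & (b != HET)
    a_u, b_u, pos_u = a[usable], b[usable], pos[usable]
    segs = []
    if a_u.size:
        mismatch = a_u != b_u
        for s, e in _window_runs(mismatch, params.window, params.ibd1_max_ibs0):
            start, end = int(pos_u[s]) - 1, int(pos_u[e])
            if e - s + 1 >= params.min_markers:
                segs.append((start, end))
    longest = max((e - s for s, e in segs), default=0)
    return XSegmentReport(
        pair=pair, longest_bp=longest,
        passes_threshold=longest >= threshold_bp,
        n_markers_used=int(a_u.size), segments=tuple(segs),
    )


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def segments_to_bed_rows(segments: list[IBDSegment]):
    for seg in segments:
        yield seg.chrom, seg.start, seg.end, seg.state


def write_segments_bed(segments: list[IBDSegment], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, name in segments_to_bed_rows(segments):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
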
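"""Interval algebra over genomic segments: merge, k-way intersection, BED I/O.

All coordinates are 0-based half-open, the BED convention.  An
:class:`IntervalSet` keeps, per chromosome, a sorted array of disjoint
non-abutting intervals, so set operations are simple breakpoint sweeps.  The
multi-way intersection is the operation used to find regions shared IBD by
every individual: each pair's segments are flattened to one set and the sets
are intersected across all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel, is_x_name


class CoordinateError(ValueError):
    pass


class BedParseError(ValueError):
    pass


def _normalize_pairs(pairs) -> np.ndarray:
    """Sort and merge overlapping/abutting (start, end) pairs."""
    arr = np.asarray(sorted((int(s), int(e)) for s, e in pairs), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    bad = arr[arr[:, 1] <= arr[:, 0]]
    if bad.size:
        s, e = bad[0]
        raise CoordinateError(f"interval end must exceed start: ({s}, {e})")
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:  # overlap or abutting
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass(frozen=True)
class IntervalSet:
    """Per-chromosome sorted disjoint half-open intervals."""

    by_chrom: dict[str, np.ndarray]  # chrom -> (n, 2) int64, normalized

    @classmethod
    def from_iterable(cls, items) -> "IntervalSet":
        """Build from (chrom, start, end) triples; normalizes on the way in."""
        raw: dict[str, list] = {}
        for chrom, s, e in items:
            raw.setdefault(str(chrom), []).append((s, e))
        return cls({c: _normalize_pairs(v) for c, v in raw.items() if v})

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls({})

    def __iter__(self):
        for chrom in self.by_chrom:
            for s, e in self.by_chrom[chrom]:
                yield chrom, int(s), int(e)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = {c: v for c, v in self.by_chrom.items() if v.size}
        b = {c: v for c, v in other.by_chrom.items() if v.size}
        return a.keys() == b.keys() and all(
            np.array_equal(a[c], b[c]) for c in a)

    @property
    def n_intervals(self) -> int:
        return sum(v.shape[0] for v in self.by_chrom.values())

    @property
    def total_bp(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self.by_chrom.values()))

    def chrom_bp(self, chrom: str) -> int:
        v = self.by_chrom.get(chrom)
        return int((v[:, 1] - v[:, 0]).sum()) if v is not None and v.size else 0

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        v = self.by_chrom.get(chrom)
        if v is None or v.size == 0:
            return False
        i = int(np.searchsorted(v[:, 0], pos0, side="right")) - 1
        return i >= 0 and pos0 < v[i, 1]

    def lengths(self) -> np.ndarray:
        out = [v[:, 1] - v[:, 0] for v in self.by_chrom.values() if v.size]
        return np.concatenate(out) if out else np.array([], dtype=np.int64)


def normalize(intervals) -> IntervalSet:
    """Normalize (chrom, start, end) triples or an IntervalSet: sorted,
    overlapping/abutting intervals merged.  Idempotent."""
    if isinstance(intervals, IntervalSet):
        return IntervalSet.from_iterable(iter(intervals))
    return IntervalSet.from_iterable(intervals)


def _intersect_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return (np.asarray(out, dtype=np.int64) if out
            else np.zeros((0, 2), dtype=np.int64))


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    common = set(a.by_chrom) & set(b.by_chrom)
    return IntervalSet({
        c: r for c in common
        if (r := _intersect_pairs(a.by_chrom[c], b.by_chrom[c])).size
    })


def intersect_all(sets: list[IntervalSet]) -> IntervalSet:
    """Exact k-way intersection (associative and commutative)."""
    if not sets:
        raise ValueError("need at least one interval set")
    acc = sets[0]
    for other in sets[1:]:
        acc = intersect(acc, other)
    return acc


def union(sets: list[IntervalSet]) -> IntervalSet:
    items = [t for s in sets for t in s]
    return IntervalSet.from_iterable(items)


@dataclass(frozen=True)
class SharedRegionReport:
    """Summary of a set of shared regions."""

    n_segments: int
    total_bp: int
    mean_bp: float
    fraction_autosomal: float

    def as_dict(self) -> dict:
        return {
            "n_segments": self.n_segments,
            "total_bp": self.total_bp,
            "total_mb": self.total_bp / 1e6,
            "mean_bp": self.mean_bp,
            "mean_mb": self.mean_bp / 1e6,
            "fraction_autosomal": self.fraction_autosomal,
        }


def summarize(regions: IntervalSet, model: GenomeModel) -> SharedRegionReport:
    """Counts, span and the fraction of the autosomal genome covered.

    The fraction counts only autosomal intervals against the autosomal
    genome length; counts and span cover all intervals.
    """
    n = regions.n_intervals
    total = regions.total_bp
    auto_bp = sum(regions.chrom_bp(c.name) for c in model.autosomes)
    return SharedRegionReport(
        n_segments=n,
        total_bp=total,
        mean_bp=total / n if n else 0.0,
        fraction_autosomal=auto_bp / model.autosome_length,
    )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read BED3+ (0-based half-open); tolerates track/browser/comment lines."""
    items = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if e <= s:
                raise BedParseError(
                    f"{path}:{lineno}: end {e} <= start {s}")
            items.append((fields[0], s, e))
    return IntervalSet.from_iterable(items)


def write_bed(regions: IntervalSet, path, names=None) -> None:
    """Write BED3 (or BED4 when ``names`` supplies one name per interval)."""
    with open(path, "w") as fh:
        for k, (chrom, s, e) in enumerate(regions):
            if names is not None:
                fh.write(f"{chrom}\t{s}\t{e}\t{names[k]}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\n")
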
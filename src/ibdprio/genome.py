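"""Genome models: chromosome layout, genetic map, marker grids and founder MAFs.

A :class:`GenomeModel` describes the coordinate system every other module works
in: an ordered list of chromosomes (at most one flagged as X), a uniform
recombination rate in cM/Mb, a marker density, and the distribution founder
minor-allele frequencies are drawn from.  Physical coordinates are base pairs;
marker positions are 1-based (VCF convention) while all interval types are
0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GenomeError(ValueError):
    """Raised for an inconsistent genome model or marker configuration."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    is_x: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise GenomeError(f"chromosome {self.name}: length must be > 0")


# Approximate hg19 chromosome lengths, megabases.
_HG19_AUTOSOME_MB = (
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
    135, 134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51,
)
_HG19_X_MB = 155

_MAF_LAWS = ("uniform", "fixed", "beta")


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome layout plus the parameters of the simulated marker panel.

    Parameters
    ----------
    chromosomes
        Ordered chromosomes; zero or one may be flagged ``is_x``.
    cm_per_mb
        Uniform recombination rate (1 cM/Mb approximates the human average).
    markers_per_mb
        Density of the regular bi-allelic SNV grid used for simulation.
    maf_law
        Distribution of founder minor-allele frequencies:
        ``("uniform", lo, hi)``, ``("fixed", p)`` or ``("beta", a, b)``.
    """

    chromosomes: tuple[Chromosome, ...]
    cm_per_mb: float = 1.0
    markers_per_mb: float = 100.0
    maf_law: tuple = ("uniform", 0.05, 0.5)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise GenomeError("genome model needs at least one chromosome")
        if self.cm_per_mb < 0:
            raise GenomeError("recombination rate must be >= 0")
        if self.markers_per_mb <= 0:
            raise GenomeError("marker density must be > 0")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")
        if sum(c.is_x for c in self.chromosomes) > 1:
            raise GenomeError("at most one chromosome may be flagged X")
        if self.maf_law[0] not in _MAF_LAWS:
            raise GenomeError(f"unknown MAF law {self.maf_law[0]!r}")

    # -- lookups -----------------------------------------------------------

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise GenomeError(f"unknown chromosome {name!r}")

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if not c.is_x)

    @property
    def x_chromosome(self) -> Chromosome | None:
        for c in self.chromosomes:
            if c.is_x:
                return c
        return None

    @property
    def autosome_length(self) -> int:
        return sum(c.length_bp for c in self.autosomes)

    def morgans(self, chrom: Chromosome) -> float:
        """Genetic length of a chromosome in Morgans under the uniform map."""
        return chrom.length_bp / 1e6 * self.cm_per_mb / 100.0

    # -- marker panel ------------------------------------------------------

    def marker_positions(self, chrom: Chromosome) -> np.ndarray:
        """Regular 1-based marker grid for one chromosome."""
        spacing = int(round(1e6 / self.markers_per_mb))
        pos = np.arange(spacing, chrom.length_bp, spacing, dtype=np.int64)
        if pos.size == 0:
            raise GenomeError(
                f"chromosome {chrom.name}: no markers at density "
                f"{self.markers_per_mb}/Mb"
            )
        return pos

    def draw_mafs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        law, *params = self.maf_law
        if law == "fixed":
            return np.full(n, float(params[0]))
        if law == "uniform":
            return rng.uniform(params[0], params[1], size=n)
        return rng.beta(params[0], params[1], size=n)


@dataclass(frozen=True)
class MarkerSet:
    """Concrete marker panel: positions, alleles and founder MAFs per chromosome."""

    model: GenomeModel
    positions: dict[str, np.ndarray]  # 1-based bp
    mafs: dict[str, np.ndarray]       # alt-allele frequency in founders
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]

    def n_markers(self, chrom: str) -> int:
        return self.positions[chrom].size

    @property
    def total_markers(self) -> int:
        return sum(p.size for p in self.positions.values())


_BASES = np.array(list("ACGT"))


def build_markers(model: GenomeModel, rng: np.random.Generator) -> MarkerSet:
    """Instantiate the marker panel for a model, drawing MAFs from its law."""
    positions, mafs, refs, alts = {}, {}, {}, {}
    for chrom in model.chromosomes:
        pos = model.marker_positions(chrom)
        n = pos.size
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        positions[chrom.name] = pos
        mafs[chrom.name] = model.draw_mafs(n, rng)
        refs[chrom.name] = _BASES[ref_idx]
        alts[chrom.name] = _BASES[alt_idx]
    return MarkerSet(model, positions, mafs, refs, alts)


def default_genome(markers_per_mb: float = 100.0, cm_per_mb: float = 1.0,
                   maf_law: tuple = ("uniform", 0.05, 0.5)) -> GenomeModel:
    """hg19-like genome: 22 autosomes plus a 155 Mb X."""
    chroms = [Chromosome(str(i + 1), mb * 1_000_000)
              for i, mb in enumerate(_HG19_AUTOSOME_MB)]
    chroms.append(Chromosome("X", _HG19_X_MB * 1_000_000, is_x=True))
    return GenomeModel(tuple(chroms), cm_per_mb, markers_per_mb, maf_law)


def demo_genome(n_autosomes: int = 6, autosome_mb: float = 150.0,
                x_mb: float = 155.0, markers_per_mb: float = 50.0,
                cm_per_mb: float = 1.0,
                maf_law: tuple = ("uniform", 0.05, 0.5)) -> GenomeModel:
    """Scaled-down genome used by the demo pipeline and simulation tests.

    Six 150 Mb autosomes keep expectation-level statistics (kinship, sharing
    fractions) meaningful while the whole chain runs in seconds.
    """
    chroms = [Chromosome(str(i + 1), int(autosome_mb * 1e6))
              for i in range(n_autosomes)]
    if x_mb:
        chroms.append(Chromosome("X", int(x_mb * 1e6), is_x=True))
    return GenomeModel(tuple(chroms), cm_per_mb, markers_per_mb, maf_law)


def is_x_name(name: str) -> bool:
    return name in ("X", "chrX", "23", "x")
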
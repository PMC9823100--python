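"""Genotype matrix container and VCF/PED text I/O.

Unphased calls are stored as a dense ``int8`` array, one row per sample, one
column per marker: 0 = homozygous reference, 1 = heterozygous, 2 = homozygous
alternate, -1 = missing.  Male X calls are hemizygous but encoded with the
homozygous diploid codes (0/2); the VCF writer emits them as single-allele
genotypes and the reader restores the same encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import is_x_name

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


class MatrixError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Per-sample, per-marker unphased genotype calls.

    ``markers`` is a DataFrame with columns chrom / pos (1-based) / ref / alt,
    sorted by position within each chromosome.  ``sex`` maps sample id to
    'M'/'F' and is required for X-chromosome operations.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise MatrixError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)

    # -- basic access ------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def calls_for(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def is_x(self) -> np.ndarray:
        """Boolean mask over markers: True where the marker is on chromosome X."""
        return self.markers["chrom"].map(is_x_name).to_numpy(dtype=bool)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            list(self.samples),
            self.markers.loc[mask].reset_index(drop=True),
            self.calls[:, mask].copy(),
            dict(self.sex),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_DIPLOID_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
# hemizygous male X; a heterozygous call (genotyping artifact) stays diploid
_HAPLOID_GT = {HOM_REF: "0", HET: "0/1", HOM_ALT: "1", MISSING: "."}


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None,
              timestamp: bool = False) -> None:
    """Write a minimal VCFv4.2 with GT-only FORMAT.

    ``timestamp=False`` (the default) omits the fileDate header line so that
    identical inputs produce byte-identical files.
    """
    chroms = list(dict.fromkeys(matrix.markers["chrom"]))
    if contig_lengths is None:
        contig_lengths = {
            c: int(matrix.markers.loc[matrix.markers["chrom"] == c, "pos"].max())
            for c in chroms
        }
    male = np.array([matrix.sex.get(s) == "M" for s in matrix.samples])
    xmask = matrix.is_x()
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if timestamp:
                import datetime
                fh.write(f"##fileDate={datetime.date.today():%Y%m%d}\n")
            fh.write("##source=ibdprio\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(matrix.samples) + "\n")
            rows = matrix.markers.itertuples(index=False)
            for j, rec in enumerate(rows):
                haploid = xmask[j]
                gts = [
                    (_HAPLOID_GT if (haploid and male[i]) else _DIPLOID_GT)[
                        int(matrix.calls[i, j])]
                    for i in range(len(matrix.samples))
                ]
                fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}"
                         f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


def read_vcf(path, sex: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix via cyvcf2.

    Only bi-allelic records are accepted; genotypes other than GT are ignored.
    Haploid male-X genotypes are re-encoded with the homozygous diploid codes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, pos, ref, alt, calls = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise MatrixError(
                f"{path}: only bi-allelic records supported at {v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        calls.append(g)
    vcf.close()
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(pos, dtype=np.int64),
         "ref": ref, "alt": alt})
    arr = (np.vstack(calls).T if calls
           else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, markers, arr, dict(sex or {}))


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODE = {"M": "1", "F": "2"}
_SEX_DECODE = {"1": "M", "2": "F"}


def write_ped(rows, path, family: str = "FAM1") -> None:
    """Write a six-column PED file.

    ``rows`` is an iterable of (id, sex 'M'/'F', father or None, mother or
    None, affected bool).
    """
    with open(path, "w") as fh:
        for iid, sex, father, mother, affected in rows:
            fh.write("\t".join([
                family, iid, father or "0", mother or "0",
                _SEX_CODE.get(sex, "0"), "2" if affected else "1",
            ]) + "\n")


def read_ped(path) -> pd.DataFrame:
    """Read a six-column PED file into a DataFrame (sex decoded to 'M'/'F')."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["family", "iid", "father", "mother", "sex", "phenotype"],
                     dtype=str)
    df["sex"] = df["sex"].map(_SEX_DECODE).fillna("U")
    df["affected"] = df["phenotype"] == "2"
    for col in ("father", "mother"):
        df[col] = df[col].replace("0", pd.NA)
    return df


def ped_sex_map(path) -> dict[str, str]:
    df = read_ped(path)
    return dict(zip(df["iid"], df["sex"]))
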
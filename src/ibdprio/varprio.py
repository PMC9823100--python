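"""Rare-variant filtering and prioritization inside shared IBD regions.

Variants live in a pandas DataFrame (one row per variant) joined from a
multi-sample VCF and an annotation sidecar table keyed by
chrom/pos/ref/alt.  The filtering chain mirrors a family-based monogenic
disease search: restrict to regions shared IBD by all affected individuals,
drop variants common in population databases (gnomAD), keep protein-coding
impacts, and screen missense candidates with a three-tool in-silico
deleteriousness consensus (SIFT, PolyPhen2 HumDiv, PROVEAN).

Population-frequency columns use NaN for "absent from gnomAD"; absence is
treated as frequency 0, so novel variants always survive an AF threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet

CODING_IMPACTS = ("stop-gain", "frameshift", "splicing", "missense", "synonymous")
# severity ranking used when an annotation lists several impacts
IMPACT_RANK = {imp: k for k, imp in enumerate(
    ("stop-gain", "frameshift", "splicing", "missense", "synonymous",
     "non-coding"))}

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

ANNOTATION_COLUMNS = [
    "gene", "impact", "hgvs_c", "hgvs_p", "af_overall", "af_nfe",
    "sift", "polyphen2_hdiv", "provean",
]


class AnnotationError(ValueError):
    pass


class UsageError(ValueError):
    pass


@dataclass
class FilterTrace:
    """Telescoping record of each filter stage."""

    stages: list[dict] = field(default_factory=list)
    max_ids: int = 1000  # cap stored removed ids per stage (counts are exact)

    def add(self, name: str, n_in: int, n_out: int, removed_ids: list[str]) -> None:
        if self.stages and self.stages[-1]["surviving"] != n_in:
            raise ValueError(
                f"stage {name!r}: input {n_in} != previous surviving "
                f"{self.stages[-1]['surviving']}")
        removed = list(removed_ids)
        self.stages.append({
            "stage": name, "input": n_in, "surviving": n_out,
            "n_removed": len(removed),
            "removed": removed[: self.max_ids],
        })

    @property
    def telescopes(self) -> bool:
        return all(
            s["surviving"] == t["input"]
            for s, t in zip(self.stages[:-1], self.stages[1:]))

    def to_json(self) -> str:
        return json.dumps(self.stages, indent=2)


def variant_ids(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"])


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_annotations(tsv_path) -> pd.DataFrame:
    ann = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_KEY if c not in ann.columns]
    if missing:
        raise AnnotationError(f"{tsv_path}: missing key columns {missing}")
    if ann.duplicated(VARIANT_KEY).any():
        dup = ann.loc[ann.duplicated(VARIANT_KEY), VARIANT_KEY].iloc[0]
        raise AnnotationError(
            f"{tsv_path}: duplicate annotation key "
            f"{dup.chrom}:{dup.pos}:{dup.ref}:{dup.alt}")
    return ann


def load_variants(vcf_path, annotation_tsv) -> pd.DataFrame:
    """Join VCF records with the annotation sidecar table.

    Carriers are samples with at least one alternate allele.  VCF records
    without an annotation row are kept with impact 'non-coding' and absent
    population frequencies.
    """
    from .matrix import read_vcf

    matrix = read_vcf(vcf_path)
    df = matrix.markers.copy()
    df["chrom"] = df["chrom"].astype(str)
    carrier_lists = []
    for j in range(matrix.n_markers):
        col = matrix.calls[:, j]
        carrier_lists.append(
            [s for i, s in enumerate(matrix.samples) if col[i] in (1, 2)])
    df["carriers"] = [",".join(c) for c in carrier_lists]
    df["n_carriers"] = [len(c) for c in carrier_lists]
    ann = load_annotations(annotation_tsv)
    merged = df.merge(ann, on=VARIANT_KEY, how="left")
    merged["impact"] = merged["impact"].fillna("non-coding")
    for col in ANNOTATION_COLUMNS:
        if col not in merged.columns:
            merged[col] = np.nan
    return merged


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_af(variants: pd.DataFrame, threshold: float = 0.01,
              policy: str = "overall") -> pd.DataFrame:
    """Keep variants with population allele frequency strictly below threshold.

    policy='overall' uses the overall gnomAD frequency; policy='popmax' uses
    the maximum of the available population columns.  Absence from gnomAD
    (NaN) counts as frequency 0.
    """
    if policy not in ("overall", "popmax"):
        raise UsageError(f"unknown AF policy {policy!r}")
    overall = variants["af_overall"].fillna(0.0)
    if policy == "overall":
        af = overall
    else:
        af = pd.concat(
            [overall, variants["af_nfe"].fillna(0.0)], axis=1).max(axis=1)
    return variants.loc[af < threshold].reset_index(drop=True)


def filter_regions(variants: pd.DataFrame, shared: IntervalSet) -> pd.DataFrame:
    """Keep variants whose (1-based) position falls in the shared regions
    (0-based half-open membership)."""
    keep = [
        shared.contains(str(row.chrom), int(row.pos) - 1)
        for row in variants.itertuples(index=False)
    ]
    return variants.loc[keep].reset_index(drop=True)


def select_coding(variants: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Coding subset plus a histogram of impact classes."""
    coding = variants.loc[variants["impact"].isin(CODING_IMPACTS)]
    hist = coding["impact"].value_counts().to_dict()
    return coding.reset_index(drop=True), hist


# ---------------------------------------------------------------------------
# In-silico consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusThresholds:
    """Deleteriousness cutoffs in each tool's native convention."""

    sift_max: float = 0.05           # lower = more damaging
    polyphen2_hdiv_min: float = 0.957  # "probably damaging" HumDiv cutoff
    provean_max: float = -2.5        # lower = more damaging


DEFAULT_THRESHOLDS = ConsensusThresholds()


def consensus_deleterious(variant, thresholds: ConsensusThresholds = DEFAULT_THRESHOLDS
                          ) -> tuple[bool, dict[str, bool]]:
    """True iff SIFT, PolyPhen2 and PROVEAN all call the variant deleterious.

    ``variant`` is a mapping/Series with sift, polyphen2_hdiv, provean and
    impact fields.  A missing score counts as not-deleterious for that tool.
    Only meaningful for missense variants; anything else is a usage error.
    """
    impact = variant["impact"]
    if impact != "missense":
        raise UsageError(
            f"consensus screen applies to missense variants, got {impact!r}")

    def _ok(value, pred) -> bool:
        return value is not None and not pd.isna(value) and pred(float(value))

    verdicts = {
        "sift": _ok(variant.get("sift"), lambda v: v <= thresholds.sift_max),
        "polyphen2_hdiv": _ok(variant.get("polyphen2_hdiv"),
                              lambda v: v >= thresholds.polyphen2_hdiv_min),
        "provean": _ok(variant.get("provean"),
                       lambda v: v <= thresholds.provean_max),
    }
    return all(verdicts.values()), verdicts


# ---------------------------------------------------------------------------
# Pipeline + report
# ---------------------------------------------------------------------------

def prioritize(variants: pd.DataFrame, shared: IntervalSet,
               af_threshold: float = 0.01, af_policy: str = "overall"
               ) -> tuple[pd.DataFrame, dict[str, int], FilterTrace]:
    """AF filter -> shared-region filter -> coding filter, with a trace."""
    trace = FilterTrace()

    def _step(name, before, after):
        lost = set(variant_ids(before)) - set(variant_ids(after))
        trace.add(name, len(before), len(after), sorted(lost))

    rare = filter_af(variants, af_threshold, af_policy)
    _step(f"af<{af_threshold} ({af_policy})", variants, rare)
    in_region = filter_regions(rare, shared)
    _step("shared-IBD regions", rare, in_region)
    coding, hist = select_coding(in_region)
    _step("coding impact", in_region, coding)
    return coding, hist, trace


def _fmt_af(row) -> str:
    if pd.isna(row["af_overall"]):
        return "absent"
    nfe = "" if pd.isna(row["af_nfe"]) else f" ({row['af_nfe']:g})"
    return f"{row['af_overall']:g}{nfe}"


def report(variants: pd.DataFrame, trace: FilterTrace,
           tsv_path=None, json_path=None) -> pd.DataFrame:
    """Render the prioritized variants as a publication-style table.

    Columns: variant key, gene, impact class, HGVS, gnomAD AF overall with
    the non-Finnish-European frequency in brackets, carrier count.
    """
    out = pd.DataFrame({
        "variant": variant_ids(variants) if len(variants) else
        pd.Series([], dtype=str),
        "gene": variants.get("gene", pd.Series([], dtype=str)),
        "impact": variants.get("impact", pd.Series([], dtype=str)),
        "hgvs": (variants["hgvs_c"].fillna("") + ":" + variants["hgvs_p"].fillna("")
                 if len(variants) else pd.Series([], dtype=str)),
        "gnomad_af": ([_fmt_af(r) for _, r in variants.iterrows()]
                      if len(variants) else pd.Series([], dtype=str)),
        "n_carriers": variants.get("n_carriers", pd.Series([], dtype=int)),
    })
    if tsv_path is not None:
        out.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            fh.write(trace.to_json())
    return out
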
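"""Accessors for the packaged text fixtures.

The variant fixture reproduces the published table of eight rare coding
variants shared IBD by all four sequenced individuals, embedded among decoy
records that each filter stage removes.  The shared-region BED is a synthetic
stand-in for the nine shared segments (the study's own coordinates are not
public); it covers the eight variant positions and matches the published
count, total span and mean length.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def fixture_path(name: str) -> Path:
    ref = resources.files("ibdprio") / "data" / name
    return Path(str(ref))


def table2_vcf() -> Path:
    return fixture_path("table2_variants.vcf")


def table2_annotations() -> Path:
    return fixture_path("table2_annotations.tsv")


def shared_segments_bed() -> Path:
    return fixture_path("shared_segments.bed")


def family_ped() -> Path:
    return fixture_path("family.ped")


def p81s_evidence_yaml() -> Path:
    return fixture_path("p81s_evidence.yaml")


def pax_screen_tsv() -> Path:
    return fixture_path("pax_missense_screen.tsv")
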
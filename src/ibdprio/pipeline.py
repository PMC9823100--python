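"""End-to-end orchestration: config validation, the demo chain, manifests.

The demo chain mirrors the study design on synthetic data: simulate the
two-sib-pair pedigree (mothers full sisters), inject a rare coding variant on
a founder haplotype shared by all four probands, detect pairwise IBD
segments from the noisy unphased genotypes, intersect them across all six
pairs, prioritize variants inside the shared regions, and classify the
candidate with the ACMG/AMP rules and Bayesian odds.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acmg, ibd, intervals, pedsim, varprio
from .genome import demo_genome
from .pedsim import PROBANDS, canonical_two_family_pedigree


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {
        "n_autosomes": 6,
        "autosome_mb": 150.0,
        "x_mb": 155.0,
        "markers_per_mb": 50.0,
        "cm_per_mb": 1.0,
        "maf": ["uniform", 0.05, 0.5],
    },
    "simulate": {
        "error_rate": 0.002,
        "missing_rate": 0.002,
    },
    "detector": {
        "window": 100,
        "ibs0_tol": 1,
        "ibd2_tol": 5,
        "min_length_mb": 5.0,
        "x_min_length_mb": 10.0,
        "min_markers": 100,
    },
    "filters": {
        "af_threshold": 0.01,
        "af_policy": "overall",
    },
    "odds": {
        "prior": 0.10,
        "rounded": True,
    },
}

_RATE_FIELDS = (("simulate", "error_rate"), ("simulate", "missing_rate"))


def load_config(path=None) -> dict:
    """Load a YAML config merged over the shipped defaults."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, block in user.items():
            if isinstance(block, dict) and isinstance(config.get(key), dict):
                config[key].update(block)
            else:
                config[key] = block
    return config


def validate_config(config: dict) -> list[str]:
    """Return a list of problems; an empty list means the config is valid."""
    problems = []
    for key in config:
        if key not in DEFAULT_CONFIG:
            problems.append(f"unknown config key {key!r}")
    for key, block in config.items():
        if key in DEFAULT_CONFIG and isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(block, dict):
                problems.append(f"{key}: expected a mapping")
                continue
            for sub in block:
                if sub not in DEFAULT_CONFIG[key]:
                    problems.append(f"unknown config key {key}.{sub!r}")
    seed = config.get("seed")
    if seed is None:
        problems.append("seed: missing (every stochastic step needs a seed)")
    elif not isinstance(seed, int) or seed < 0:
        problems.append(f"seed: must be a non-negative integer, got {seed!r}")
    for block, field in _RATE_FIELDS:
        value = config.get(block, {}).get(field)
        if value is not None and not 0 <= value <= 1:
            problems.append(f"{block}.{field}: {value} outside [0, 1]")
    policy = config.get("filters", {}).get("af_policy")
    if policy not in (None, "overall", "popmax"):
        problems.append(f"filters.af_policy: unknown policy {policy!r}")
    thr = config.get("filters", {}).get("af_threshold")
    if thr is not None and not 0 < thr <= 1:
        problems.append(f"filters.af_threshold: {thr} outside (0, 1]")
    return problems


def _detector_params(block: dict) -> ibd.DetectorParams:
    return ibd.DetectorParams(
        window=int(block["window"]),
        ibd1_max_ibs0=int(block["ibs0_tol"]),
        ibd2_max_non_ibs2=int(block["ibd2_tol"]),
        min_length_bp=int(block["min_length_mb"] * 1e6),
        min_length_bp_x=int(block["x_min_length_mb"] * 1e6),
        min_markers=int(block["min_markers"]),
    )


def _genome_from_config(block: dict):
    return demo_genome(
        n_autosomes=int(block["n_autosomes"]),
        autosome_mb=float(block["autosome_mb"]),
        x_mb=float(block["x_mb"]),
        markers_per_mb=float(block["markers_per_mb"]),
        cm_per_mb=float(block["cm_per_mb"]),
        maf_law=tuple(block["maf"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()


def run_demo(config: dict, outdir) -> dict:
    """Run the full chain; returns the manifest (also written to disk)."""
    problems = validate_config(config)
    if problems:
        raise StageError("config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "ibdprio",
        "config_hash": _config_hash(config),
        "stages": {},
        "files": {},
    }
    files: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"{name}: {exc}") from exc
        return wrap

    # ---- simulate --------------------------------------------------------
    def _simulate():
        model = _genome_from_config(config["genome"])
        spec = canonical_two_family_pedigree()
        sim = config["simulate"]
        matrix, truth = pedsim.simulate_pedigree(
            spec, model, error_rate=sim["error_rate"],
            missing_rate=sim["missing_rate"], seed=config["seed"],
            samples=list(PROBANDS))
        return model, spec, matrix, truth

    model, spec, matrix, truth = _stage("simulate")(_simulate)

    # ---- inject the candidate variant ------------------------------------
    def _inject():
        shared_truth = truth.shared_by_all_intervals(list(PROBANDS))
        best = max(
            ((chrom, s, e) for chrom, ivals in shared_truth.items()
             for s, e in ivals),
            key=lambda t: t[2] - t[1], default=None)
        if best is None:
            raise StageError(
                "inject: no four-way shared founder segment in this replicate; "
                "re-run with a different seed")
        chrom, s, e = best
        pos = (s + e) // 2 + 7  # off the regular marker grid
        label = sorted(truth.common_label_at(list(PROBANDS), chrom, pos - 1))[0]
        annotation = {
            "gene": "CAND1", "impact": "missense",
            "hgvs_c": "c.241C>T", "hgvs_p": "p.P81S",
            "af_overall": None, "af_nfe": None,
            "sift": 0.0, "polyphen2_hdiv": 0.99, "provean": -5.0,
        }
        return pedsim.inject_candidate_variant(
            matrix, truth, label, chrom, int(pos), "C", "T", annotation)

    matrix, carriers, cand_ann = _stage("inject")(_inject)
    cand_id = f"{cand_ann['chrom']}:{cand_ann['pos']}:C:T"
    manifest["stages"]["inject"] = {
        "candidate": cand_id, "carriers": carriers}

    # ---- write simulated inputs ------------------------------------------
    def _write_inputs():
        paths = pedsim.write_outputs(matrix, spec, truth, outdir, prefix="sim")
        # annotation sidecar: candidate + two common missense decoys
        mk = matrix.markers
        decoy_rows = []
        auto = mk.loc[~matrix.is_x()]
        for k, idx in enumerate((len(auto) // 3, 2 * len(auto) // 3)):
            r = auto.iloc[idx]
            decoy_rows.append({
                "chrom": r["chrom"], "pos": int(r["pos"]), "ref": r["ref"],
                "alt": r["alt"], "gene": f"DECOY{k + 1}", "impact": "missense",
                "hgvs_c": "", "hgvs_p": "", "af_overall": 0.2, "af_nfe": 0.2,
                "sift": 0.8, "polyphen2_hdiv": 0.1, "provean": 0.0,
            })
        ann = pd.DataFrame([cand_ann, *decoy_rows])
        paths["annotations"] = outdir / "sim.annotations.tsv"
        ann.to_csv(paths["annotations"], sep="\t", index=False)
        return paths

    files.update(_stage("write-inputs")(_write_inputs))

    # ---- pairwise IBD ----------------------------------------------------
    def _detect():
        params = _detector_params(config["detector"])
        results = ibd.analyze_pairs(matrix, model, params, list(PROBANDS))
        table = ibd.sharing_table(results)
        files["pair_stats"] = outdir / "pair_stats.tsv"
        table.to_csv(files["pair_stats"], sep="\t", index=False)
        for pair, (segs, _) in results.items():
            p = outdir / f"segments.{pair[0]}_{pair[1]}.bed"
            ibd.write_segments_bed(segs, p)
            files[f"segments_{pair[0]}_{pair[1]}"] = p
        return params, results, table

    params, results, table = _stage("ibd-detect")(_detect)
    manifest["stages"]["ibd"] = {
        "n_pairs": len(results),
        "n_segments": int(sum(len(s) for s, _ in results.values())),
    }

    # ---- intersection ----------------------------------------------------
    def _intersect():
        auto_names = {c.name for c in model.autosomes}
        sets = []
        for pair, (segs, _) in results.items():
            sets.append(intervals.IntervalSet.from_iterable(
                (g.chrom, g.start, g.end) for g in segs
                if g.chrom in auto_names))
        shared = intervals.intersect_all(sets)
        files["shared_bed"] = outdir / "shared.bed"
        intervals.write_bed(shared, files["shared_bed"])
        summary = intervals.summarize(shared, model).as_dict()
        files["shared_summary"] = outdir / "shared_summary.json"
        files["shared_summary"].write_text(json.dumps(summary, indent=2))
        return shared, summary

    shared, shared_summary = _stage("intersect")(_intersect)
    manifest["stages"]["intersect"] = shared_summary

    # ---- X male-male sharing ---------------------------------------------
    def _xshare():
        males = [s for s in PROBANDS if matrix.sex.get(s) == "M"]
        filtered = ibd.x_male_filter(matrix, males)
        reports = []
        threshold = int(config["detector"]["x_min_length_mb"] * 1e6)
        for i, a in enumerate(males):
            for b in males[i + 1:]:
                rep = ibd.x_pair_segments(filtered, (a, b), threshold, params)
                reports.append({
                    "pair": list(rep.pair), "longest_bp": rep.longest_bp,
                    "passes_threshold": rep.passes_threshold,
                    "n_markers_used": rep.n_markers_used,
                })
        files["x_report"] = outdir / "x_share.json"
        files["x_report"].write_text(json.dumps(reports, indent=2))
        return reports

    manifest["stages"]["xshare"] = _stage("xshare")(_xshare)

    # ---- variant prioritization ------------------------------------------
    def _prioritize():
        variants = varprio.load_variants(files["vcf"], files["annotations"])
        coding, hist, trace = varprio.prioritize(
            variants, shared,
            af_threshold=config["filters"]["af_threshold"],
            af_policy=config["filters"]["af_policy"])
        files["prioritized"] = outdir / "prioritized.tsv"
        files["filter_trace"] = outdir / "filter_trace.json"
        rep = varprio.report(coding, trace, files["prioritized"],
                             files["filter_trace"])
        return rep, hist, trace

    rep, hist, trace = _stage("prioritize")(_prioritize)
    manifest["stages"]["prioritize"] = {
        "trace": [{k: s[k] for k in ("stage", "input", "surviving", "n_removed")}
                  for s in trace.stages],
        "histogram": hist,
        "candidate_in_report": bool((rep["variant"] == cand_id).any()),
    }

    # ---- ACMG classification ----------------------------------------------
    def _classify():
        odds_cfg = config["odds"]
        model_odds = acmg.OddsModel(prior=odds_cfg["prior"],
                                    exact=not odds_cfg["rounded"])
        evidence = acmg.EvidenceSet(acmg.P81S_EVIDENCE)
        result = acmg.classify_full(evidence, model_odds)
        payload = {"evidence": [c.code for c in evidence],
                   **result.as_dict()}
        files["acmg"] = outdir / "acmg.json"
        files["acmg"].write_text(json.dumps(payload, indent=2))
        return payload

    manifest["stages"]["acmg"] = _stage("acmg")(_classify)

    manifest["files"] = {k: str(p) for k, p in files.items()}
    manifest["checksums"] = {k: _sha256(p) for k, p in files.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
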
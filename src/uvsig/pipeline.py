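"""End-to-end orchestration of the analysis stages.

A single configuration (mapping or YAML file) drives either a fully
synthetic run (simulate section present) or a run over user-supplied
files: consensus calling -> event collapsing and classification ->
SBS96 catalog and strand bias -> signature extraction and activity
attribution -> reference-catalog matching, with optional copy-number,
survival and dosimetry stages.  Outputs are TSV tables plus a JSON
summary stamped with the configuration hash and seed; identical
configurations reproduce identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as uio
from .cna import filter_segments, genome_altered_fraction, segments_to_frame
from .comparison import match_to_catalog
from .signatures import attribute_activities, extract_with_stability
from .spectrum import (
    GeneIndex,
    assign_transcriptional_strand,
    build_sbs96,
    count_mutation_types,
    strand_bias_table,
    strand_resolved_counts,
)
from .stats import gehan_breslow_wilcoxon, survival_records_from_frame
from .variants import build_consensus, burden_per_mb, classify_events, \
    collapse_dinucleotide_events

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


DEFAULTS = {
    "seed": 0,
    "out_dir": "uvsig_out",
    "capture_size_bp": None,
    "stages": {
        "variants": True,
        "spectrum": True,
        "signatures": True,
        "comparison": False,
        "cna": False,
        "survival": False,
    },
    "signatures_params": {
        "rank_min": 1,
        "rank_max": 5,
        "n_bootstrap": 50,
        "objective": "kl",
    },
    "cna_params": {"log2_threshold": 0.2, "min_bins": 5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    """Merge a mapping or YAML file over the defaults."""
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, dict(source))


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(config: dict, key: str, stage: str):
    value = config.get(key)
    if value is None:
        raise PipelineError(f"stage {stage!r} requires config key {key!r}")
    return value


def run_pipeline(config, reference=None, callsets=None) -> dict:
    """Execute the enabled stages and write the report bundle.

    ``config`` is a mapping or YAML path (see ``load_config``).  For
    file-driven runs the config names the input paths; alternatively an
    in-memory reference bundle and per-caller call sets (as produced by
    the synthetic generator) may be passed directly.  Returns the JSON
    summary as a dict; tables are written under ``out_dir``.
    """
    config = load_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    summary: dict = {"config_hash": _config_hash(config), "seed": seed}

    # ------------------------------------------------------------ inputs
    if config.get("simulate"):
        from .synthetic import SimulationConfig, generate_reference, simulate_catalog

        sim_cfg = SimulationConfig(seed=seed, **config["simulate"])
        reference = generate_reference(sim_cfg)
        callsets_map, truth = simulate_catalog(reference, sim_cfg)
        callsets = list(callsets_map.values())
        genes = reference.genes
        regions = reference.capture_regions
        capture_size = sum(e - s for _, s, e in regions)
        summary["simulated"] = True
    else:
        if callsets is None:
            if stages.get("variants"):
                paths = _require(config, "calls", "variants")
                callsets = [
                    uio.read_vcf_calls(p, caller_id=str(i))
                    for i, p in enumerate(paths)
                ]
        if reference is None and (stages.get("variants") or stages.get("spectrum")):
            reference = uio.open_fasta(_require(config, "reference", "variants"))
        genes = (
            uio.read_genes(config["genes"]) if config.get("genes") else []
        )
        regions = (
            uio.read_regions_bed(config["regions"])
            if config.get("regions")
            else []
        )
        capture_size = config.get("capture_size_bp") or sum(
            e - s for _, s, e in regions
        )

    events = None
    catalog = None

    # ---------------------------------------------------------- variants
    if stages.get("variants"):
        if not callsets:
            raise PipelineError("stage 'variants' requires call sets")
        exclusion = (
            uio.read_exclusion_list(config["exclude"])
            if config.get("exclude")
            else ()
        )
        consensus = build_consensus(callsets, exclusion)
        events = collapse_dinucleotide_events(consensus, reference)
        events = classify_events(events, reference)
        if genes:
            gidx = GeneIndex(genes)
            for e in events:
                assign_transcriptional_strand(e, gidx)
        uio.write_events_tsv(events, out_dir / "events.tsv")
        if not capture_size:
            raise PipelineError(
                "capture_size_bp (or a region set) is required for burden"
            )
        burden = burden_per_mb(events, capture_size)
        burden.rename("snv_per_mb").to_csv(out_dir / "burden.tsv", sep="\t")
        summary["variants"] = {
            "n_consensus_calls": len(consensus),
            "n_events": len(events),
            "n_dinucleotide": sum(
                1 for e in events if e.event_kind == "dinucleotide"
            ),
            "mean_burden_per_mb": round(float(burden.mean()), 6),
        }

    # ---------------------------------------------------------- spectrum
    if stages.get("spectrum"):
        if events is None:
            raise PipelineError("stage 'spectrum' requires the variants stage")
        catalog = build_sbs96(events)
        uio.write_catalog_tsv(catalog, out_dir / "catalog_sbs96.tsv")
        count_mutation_types(events).to_csv(
            out_dir / "mutation_types.tsv", sep="\t"
        )
        tallies, excluded = strand_resolved_counts(events)
        bias = strand_bias_table(tallies)
        bias.to_csv(out_dir / "strand_bias.tsv", sep="\t", index=False)
        summary["spectrum"] = {
            "n_samples": len(catalog.sample_ids),
            "total_snv": int(catalog.counts.sum()),
            "strand_unknown": excluded,
        }

    # -------------------------------------------------------- signatures
    if stages.get("signatures"):
        if catalog is None:
            raise PipelineError(
                "stage 'signatures' requires an SBS96 catalog input"
            )
        sp = config["signatures_params"]
        sigs, report = extract_with_stability(
            catalog,
            rank_range=range(int(sp["rank_min"]), int(sp["rank_max"]) + 1),
            n_bootstrap=int(sp["n_bootstrap"]),
            seed=seed,
            objective=sp.get("objective", "kl"),
        )
        acts = attribute_activities(catalog, sigs)
        uio.write_signatures_tsv(sigs, out_dir / "signatures.tsv")
        acts.to_frame().to_csv(out_dir / "activities.tsv", sep="\t")
        report.metrics.to_csv(out_dir / "rank_selection.tsv", sep="\t")
        summary["signatures"] = {
            "selected_rank": report.selected_rank,
            "stability": {
                int(r): round(float(s), 6)
                for r, s in report.metrics["stability"].items()
            },
        }

    # -------------------------------------------------------- comparison
    if stages.get("comparison"):
        if catalog is None or "signatures" not in summary:
            raise PipelineError(
                "stage 'comparison' requires the signatures stage"
            )
        ref_path = _require(config, "reference_catalog", "comparison")
        ref_cat = uio.read_reference_catalog_tsv(ref_path)
        sim, best = match_to_catalog(
            uio.read_signatures_tsv(out_dir / "signatures.tsv"),
            ref_cat,
            n_permutations=int(config.get("n_permutations", 0)),
            seed=seed,
        )
        sim.to_csv(out_dir / "similarity_matrix.tsv", sep="\t")
        best.to_csv(out_dir / "best_matches.tsv", sep="\t", index=False)
        summary["comparison"] = {
            row["signature"]: {
                "best_match": row["best_match"],
                "cosine": round(float(row["cosine"]), 6),
            }
            for row in best.to_dict("records")
        }

    # --------------------------------------------------------------- cna
    if stages.get("cna"):
        from .cna import segments_from_frame

        seg_path = _require(config, "segments", "cna")
        seg_df = pd.read_csv(seg_path, sep="\t")
        segments = segments_from_frame(seg_df)
        cp = config["cna_params"]
        altered = filter_segments(
            segments,
            log2_threshold=float(cp["log2_threshold"]),
            min_bins=int(cp["min_bins"]),
        )
        frac = genome_altered_fraction(segments, altered)
        frac.rename("altered_fraction").to_csv(
            out_dir / "cna_fraction.tsv", sep="\t"
        )
        segments_to_frame(altered).to_csv(
            out_dir / "cna_altered.tsv", sep="\t", index=False
        )
        summary["cna"] = {
            "mean_altered_fraction": round(float(frac.mean()), 6)
        }

    # ---------------------------------------------------------- survival
    if stages.get("survival"):
        surv_path = _require(config, "survival", "survival")
        records = survival_records_from_frame(
            pd.read_csv(surv_path, sep="\t")
        )
        groups = sorted({r.group for r in records})
        control = config.get("control_group", groups[0])
        rows = []
        for g in groups:
            if g == control:
                continue
            chi2, p = gehan_breslow_wilcoxon(
                [r for r in records if r.group == control],
                [r for r in records if r.group == g],
            )
            rows.append(
                {"control": control, "group": g, "chi_square": chi2, "p": p}
            )
        pd.DataFrame(rows).to_csv(
            out_dir / "survival_tests.tsv", sep="\t", index=False
        )
        summary["survival"] = {
            r["group"]: round(r["p"], 8) for r in rows
        }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
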
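"""End-to-end orchestration: observed SeRP onsets vs model-predicted
onsets for a heterodimer, in one structured JSON report.

Stages run in order — serp, energetics, contacts, prediction,
comparison — each wrapped so a failure marks the stage (with its cause)
and skips everything downstream, leaving a valid partial report.
Identical inputs, config and seed give identical numerical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as cio
from .config import RunConfig
from .energetics import (
    aggregate_replicates,
    classify_hotspots,
    cluster_energy_fraction,
    cumulative_profile,
    linear_clusters,
)
from .exceptions import CotransError
from .prediction import (
    asymmetry_report,
    call_directionality,
    mark_codependence,
    predict_onset,
)
from .serp import analyze_orf

REPORT_SCHEMA_VERSION = 1


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _serp_stage(path, config: RunConfig, force: bool):
    profiles = cio.read_profiles(path)
    trans = [p for p in profiles if p.sample_kind == "translatome"]
    inter = [p for p in profiles if p.sample_kind == "interactome"]
    prof = analyze_orf(
        trans, inter,
        pseudocount=config.pseudocount,
        threshold=config.onset_threshold,
        stability_fraction=config.stability_fraction,
        min_pearson=config.min_pearson,
        min_reads=config.min_reads,
        force=force,
    )
    return {
        "orf_id": prof.orf_id,
        "onset_codon": prof.onset_codon,
        "peak_fold": prof.peak_fold,
        "replicate_pearson_r": prof.replicate_pearson_r,
        "passed_qc": prof.passed_qc,
        "qc_forced": force,
        "qc_reason": prof.qc_reason,
    }


def _energetics_stage(path, label, config: RunConfig, structure, chain_id):
    table = cio.read_energy_table(path, subunit_label=label)
    aggregate_replicates(table)
    hotspots = classify_hotspots(table, config.hotspot_threshold)
    clusters = linear_clusters(hotspots, table, config.cluster_gap)
    if structure is not None and clusters:
        mark_codependence(
            clusters, structure, chain_id, table,
            hbond_distance=config.hbond_distance,
            hbond_angle=config.hbond_angle,
            spatial_cutoff=config.spatial_cutoff,
        )
    profile = cumulative_profile(table)
    summary = {
        "subunit": label,
        "n_residues": table.n_residues,
        "n_rep": table.n_rep,
        "n_hotspots": len(hotspots),
        "signed_total_kcal_mol": profile.signed_total,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "span": list(c.span),
                "n_members": len(c.members),
                "total_energy_kcal_mol": c.total_energy,
                "energy_fraction": cluster_energy_fraction(c, table),
                "codependent_with": sorted(c.codependent_with),
            }
            for c in clusters
        ],
    }
    return table, clusters, summary


def run_pipeline(config: RunConfig, inputs: dict, out_dir) -> dict:
    """Execute the full analysis on the given input paths.

    ``inputs`` keys (all paths; subunits are "a" and "b"):

    * ``energy_a``, ``energy_b`` — per-residue ΔΔG CSVs (required for
      the prediction stages)
    * ``profiles_a``, ``profiles_b`` — footprint TSVs holding both
      sample kinds (optional; enables observed onsets)
    * ``structure`` with ``chain_a``/``chain_b`` ids (optional; enables
      cluster co-dependence)
    * ``label_a``, ``label_b`` — subunit display names

    Writes ``report.json`` and the resolved config to ``out_dir`` and
    returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "stages": {},
    }
    failed = False

    def run_stage(name, fn):
        nonlocal failed
        if failed:
            report["stages"][name] = {"status": "skipped"}
            return None
        try:
            result = fn()
        except (CotransError, OSError) as exc:
            failed = True
            report["stages"][name] = {
                "status": "failed",
                "cause": f"{type(exc).__name__}: {exc}",
            }
            return None
        report["stages"][name] = {"status": "ok"}
        return result

    labels = {
        "a": inputs.get("label_a", "subunit_a"),
        "b": inputs.get("label_b", "subunit_b"),
    }

    # --- observed onsets (optional; absence is not a failure) ----------
    serp_force = bool(inputs.get("serp_force", False))
    serp_results = {}
    for key in ("a", "b"):
        path = inputs.get(f"profiles_{key}")
        if path is None:
            continue
        res = run_stage(
            f"serp_{key}", lambda p=path: _serp_stage(p, config, serp_force)
        )
        if res is not None:
            serp_results[key] = res
    report["serp"] = serp_results

    # --- structure (optional) ------------------------------------------
    structure = None
    if inputs.get("structure") is not None and not failed:
        structure = run_stage(
            "structure", lambda: cio.read_structure(inputs["structure"])
        )

    # --- energetics + prediction per subunit ---------------------------
    tables, predictions = {}, {}
    for key in ("a", "b"):
        path = inputs.get(f"energy_{key}")
        chain = inputs.get(f"chain_{key}", "A" if key == "a" else "B")

        def stage(p=path, k=key, c=chain):
            if p is None:
                raise CotransError(f"missing energy table for subunit {k}")
            table, clusters, summary = _energetics_stage(
                p, labels[k], config, structure, c
            )
            pred = predict_onset(
                table, clusters,
                energy_fraction_f=config.energy_fraction_f,
                tunnel_length=config.tunnel_length,
                margin=config.margin,
            )
            return table, pred, summary

        res = run_stage(f"energetics_{key}", stage)
        if res is not None:
            tables[key], predictions[key], summary = res
            report.setdefault("energetics", {})[key] = summary

    # --- directionality + comparison -----------------------------------
    def verdict_stage():
        asym = asymmetry_report(tables["a"], tables["b"])
        return call_directionality(predictions["a"], predictions["b"], asym)

    verdict = run_stage("prediction", verdict_stage) if len(tables) == 2 else None
    if verdict is None and "prediction" not in report["stages"]:
        report["stages"]["prediction"] = {"status": "skipped"}

    if verdict is not None:
        report["prediction"] = {
            "ambiguous": verdict.ambiguous,
            "engaged_subunit": verdict.engaged_subunit,
            "engager_subunit": verdict.engager_subunit,
            "predicted_onset_codon": verdict.onset_codon,
            "detail": verdict.detail,
            "asymmetry": _jsonable(verdict.asymmetry),
            "per_subunit": {
                k: _jsonable(predictions[k]) for k in predictions
            },
        }
        # predicted vs observed comparison
        comparison = []
        label_to_key = {labels[k]: k for k in labels}
        engaged_key = label_to_key.get(verdict.engaged_subunit)
        for key in ("a", "b"):
            observed = serp_results.get(key, {}).get("onset_codon")
            predicted = (
                verdict.onset_codon if key == engaged_key else None
            )
            entry = {
                "subunit": labels[key],
                "observed_onset_codon": observed,
                "predicted_onset_codon": predicted,
            }
            if observed is not None and predicted is not None:
                diff = predicted - observed
                entry["difference_codons"] = diff
                entry["within_tunnel_tolerance"] = abs(diff) <= config.tunnel_length
            comparison.append(entry)
        report["comparison"] = comparison
        report["direction_agreement"] = None
        if engaged_key is not None and serp_results:
            observed_engaged = {
                k for k, r in serp_results.items() if r.get("onset_codon") is not None
            }
            if observed_engaged:
                report["direction_agreement"] = (
                    observed_engaged == {engaged_key}
                )

    report["ok"] = not failed
    config.to_yaml(out_dir / "config.resolved.yaml")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
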
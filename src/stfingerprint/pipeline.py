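"""End-to-end pipeline on synthetic cohorts.

One call (or ``stfingerprint run``) executes the full framework flow:

1. simulate a multi-site training cohort, an independent transfer cohort
   with unseen site names, and a signal-free control cohort;
2. z-score, stratify into folds, and train one classifier per fold;
3. apply the fold models to the transfer cohort (zero-shot transfer);
4. apply them to the signal-free cohort (specificity control);
5. compute integrated-gradients fingerprints and the top-percentile
   consensus feature mask;
6. correlate per-subject region scores with symptom-domain scores in each
   group, with FDR correction;
7. write a machine-readable JSON run report.

A single master seed fans out deterministically to per-stage seeds, so the
whole run is reproducible and stages are independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from .association import associate
from .datamodel import Cohort, save_cohort, zscore_normalize
from .evaluation import CVResult, apply_models, crossvalidate, make_folds
from .model import StDNNConfig
from .synthetic import SynthConfig, generate_cohort, generate_null_cohort, \
    generate_transfer_cohort

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _derive_seeds(master_seed: int) -> dict[str, int]:
    """Fixed fan-out of the master seed into independent per-stage seeds."""
    state = np.random.SeedSequence(master_seed).generate_state(4)
    keys = ("synth", "folds", "model", "spare")
    return {k: int(state[i] % 2**31) for i, k in enumerate(keys)}


def _check_fields(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise PipelineError(
            f"config section {section!r}: unknown field(s) {sorted(unknown)}")


def load_pipeline_config(path_or_dict) -> dict[str, Any]:
    """Load and validate the pipeline YAML configuration."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    _check_fields("<root>", raw, {"seed", "synth", "model", "cv", "transfer",
                                  "attribution", "association"})
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "synth": dict(raw.get("synth", {})),
        "model": dict(raw.get("model", {})),
        "cv": {"k": 5, "stratify_by_site": True, **raw.get("cv", {})},
        "transfer": {"n_sites": 2, "n_class0": None, "n_class1": None,
                     **raw.get("transfer", {})},
        "attribution": {"n_steps": 50, "pct": 5.0, "target_class": 1,
                        "baseline": "zeros", **raw.get("attribution", {})},
        "association": {"domains": ["rrb", "social", "communication"],
                        "alpha": 0.01, "groups": [1, 0],
                        **raw.get("association", {})},
    }
    _check_fields("synth", cfg["synth"],
                  {f.name for f in dataclasses.fields(SynthConfig)})
    _check_fields("model", cfg["model"],
                  {f.name for f in dataclasses.fields(StDNNConfig)} - {"n_regions"})
    _check_fields("cv", cfg["cv"], {"k", "stratify_by_site"})
    _check_fields("transfer", cfg["transfer"], {"n_sites", "n_class0", "n_class1"})
    _check_fields("attribution", cfg["attribution"],
                  {"n_steps", "pct", "target_class", "baseline"})
    _check_fields("association", cfg["association"],
                  {"domains", "alpha", "groups"})
    for key in ("planted_regions", "nt_range"):
        if key in cfg["synth"]:
            cfg["synth"][key] = tuple(cfg["synth"][key])
    for key in ("conv_channels", "kernel_sizes", "strides"):
        if key in cfg["model"]:
            cfg["model"][key] = tuple(cfg["model"][key])
    return cfg


def _metrics_frame(per_fold, summary, label: str) -> pd.DataFrame:
    rows = [{"fold": i, **m.as_dict()} for i, m in enumerate(per_fold)]
    rows.append({"fold": "mean", **{k: v["mean"] for k, v in summary.items()}})
    rows.append({"fold": "sd", **{k: v["sd"] for k, v in summary.items()}})
    df = pd.DataFrame(rows)
    df.insert(0, "evaluation", label)
    return df


def run_pipeline(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute the full flow; returns the run report (also written as JSON).

    Completed stage outputs are left intact if a later stage fails.
    """
    cfg = load_pipeline_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    seeds = _derive_seeds(cfg["seed"])
    os.makedirs(out_dir, exist_ok=True)

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": json.loads(json.dumps(cfg)),
        "seeds": seeds,
        "stages": {},
        "timings_s": {},
    }
    clock = {}

    def _stage(name):
        clock[name] = time.perf_counter()

    def _done(name, **paths):
        report["timings_s"][name] = round(time.perf_counter() - clock[name], 3)
        report["stages"][name] = {k: os.fspath(v) for k, v in paths.items()}

    try:
        # 1. simulate ------------------------------------------------------
        _stage("simulate")
        synth = SynthConfig(**{**cfg["synth"], "seed": seeds["synth"]})
        t_cfg = cfg["transfer"]
        transfer_sites = [f"ext{k:02d}" for k in range(t_cfg["n_sites"])]
        tr_synth = dataclasses.replace(
            synth,
            n_class0=t_cfg["n_class0"] or synth.n_class0,
            n_class1=t_cfg["n_class1"] or synth.n_class1,
        )
        cohorts = {
            "train": zscore_normalize(generate_cohort(synth)),
            "transfer": zscore_normalize(
                generate_transfer_cohort(tr_synth, transfer_sites)),
            "control": zscore_normalize(generate_null_cohort(synth)),
        }
        paths = {}
        for name, cohort in cohorts.items():
            paths[name] = save_cohort(cohort, os.path.join(out_dir, "cohorts", name))
        _done("simulate", **paths)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    try:
        # 2. fivefold CV ---------------------------------------------------
        _stage("train_cv")
        train_cohort = cohorts["train"]
        model_cfg = StDNNConfig(n_regions=train_cohort.n_regions,
                                **{**cfg["model"], "seed": seeds["model"]})
        folds = make_folds(train_cohort.labels, train_cohort.sites,
                           k=cfg["cv"]["k"], seed=seeds["folds"],
                           stratify_by_site=cfg["cv"]["stratify_by_site"])
        cv = crossvalidate(train_cohort, model_cfg, folds)
        models_dir = os.path.join(out_dir, "models")
        os.makedirs(models_dir, exist_ok=True)
        for j, m in enumerate(cv.models):
            m.save(os.path.join(models_dir, f"fold{j}.npz"))
        cv_tsv = os.path.join(out_dir, "cv_metrics.tsv")
        _metrics_frame(cv.per_fold_metrics, cv.summary, "cv").to_csv(
            cv_tsv, sep="\t", index=False)
        report["cv"] = cv.summary
        report["ldam_margins"] = _margins_used(cv, train_cohort.labels)
        _done("train_cv", models=models_dir, metrics=cv_tsv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage train_cv failed: {exc}") from exc

    try:
        # 3./4. transfer and specificity ----------------------------------
        for name, cohort in (("transfer", cohorts["transfer"]),
                             ("specificity", cohorts["control"])):
            _stage(name)
            per_model, summary = apply_models(cv.models, cohort)
            tsv = os.path.join(out_dir, f"{name}_metrics.tsv")
            _metrics_frame(per_model, summary, name).to_csv(
                tsv, sep="\t", index=False)
            report[name] = summary
            _done(name, metrics=tsv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage transfer/specificity failed: {exc}") from exc

    try:
        # 5. attribution ---------------------------------------------------
        _stage("attribute")
        a_cfg = cfg["attribution"]
        ig = attr.IGConfig(n_steps=a_cfg["n_steps"], baseline=a_cfg["baseline"],
                           target_class=a_cfg["target_class"])
        maps_by_group = {
            g: attr.attribute_cohort(cv.models, train_cohort, g, ig)
            for g in (0, 1)}
        table = attr.aggregate_group_features(
            maps_by_group[a_cfg["target_class"]], train_cohort.region_names)
        table = attr.threshold_top_features(table, a_cfg["pct"])
        attr_dir = os.path.join(out_dir, "attribution")
        os.makedirs(attr_dir, exist_ok=True)
        consensus_tsv = os.path.join(attr_dir, "consensus_scores.tsv")
        np.savetxt(consensus_tsv, table.median_scores, delimiter="\t", fmt="%.17g")
        hits_tsv = os.path.join(attr_dir, "region_hits.tsv")
        pd.DataFrame(table.region_hits,
                     columns=["region_name", "n_cells", "peak_score"]).to_csv(
            hits_tsv, sep="\t", index=False)
        planted = [train_cohort.region_names[r] for r in synth.planted_regions]
        hit_names = [h[0] for h in table.region_hits]
        # a region counts as recovered only when its share of the mask is
        # larger than chance scatter would produce (binomial enrichment),
        # so a signal-free run reports an empty recovery list
        from scipy import stats as _stats
        nt_common = table.median_scores.shape[1]
        cells = dict(zip(hit_names, (h[1] for h in table.region_hits)))
        recovered = [
            n for n in planted
            if _stats.binom.sf(cells.get(n, 0) - 1, nt_common,
                               a_cfg["pct"] / 100.0) < 0.05]
        report["attribution"] = {
            "threshold": table.threshold,
            "n_regions_identified": len(hit_names),
            "n_cells_retained": int(table.top_mask.sum()),
            "planted_regions": planted,
            "recovered_planted_regions": recovered,
        }
        _done("attribute", consensus=consensus_tsv, region_hits=hits_tsv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage attribute failed: {exc}") from exc

    try:
        # 6. association ---------------------------------------------------
        _stage("associate")
        s_cfg = cfg["association"]
        scores = {f: _region_scores_all(maps_by_group, f, train_cohort)
                  for f in range(len(cv.models))}
        tables = [associate(train_cohort, scores, s_cfg["domains"], g,
                            s_cfg["alpha"]) for g in s_cfg["groups"]]
        assoc = pd.concat(tables, ignore_index=True)
        assoc_tsv = os.path.join(out_dir, "association.tsv")
        assoc.to_csv(assoc_tsv, sep="\t", index=False)
        headline = (assoc.sort_values("q_fdr")
                    .groupby(["group", "domain"], sort=True).head(1))
        report["association_headline"] = headline.to_dict(orient="records")
        _done("associate", table=assoc_tsv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage associate failed: {exc}") from exc

    # 7. report ------------------------------------------------------------
    _stage("report")
    maj = max(np.mean(train_cohort.labels == 0), np.mean(train_cohort.labels == 1))
    se = float(np.sqrt(maj * (1 - maj) / (len(train_cohort) / folds.k)))
    report["majority_fraction"] = float(maj)
    report["chance_level_cv"] = bool(
        abs(cv.summary["accuracy"]["mean"] - maj) <= 2 * se)
    report_path = os.path.join(out_dir, "run_report.json")
    _done("report", report=report_path)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _margins_used(cv: CVResult, labels: np.ndarray) -> list[dict]:
    """Per-fold training class counts and LDAM margin vectors."""
    from .model import ldam_margins
    out = []
    for j, m in enumerate(cv.models):
        counts = np.bincount(labels[cv.folds.train_indices(j)], minlength=2)
        if m.config.loss == "ldam":
            margins = ldam_margins(counts, m.config.ldam_C,
                                   m.config.ldam_max_margin).tolist()
        else:
            margins = [0.0, 0.0]
        out.append({"fold": j, "class_counts": counts.tolist(),
                    "margins": margins})
    return out


def _region_scores_all(maps_by_group, fold: int, cohort: Cohort) -> np.ndarray:
    """(n_subjects, n_regions) region scores for one fold model, cohort order."""
    by_id = {}
    for g, per_fold in maps_by_group.items():
        for m in per_fold[fold]:
            by_id[m.subject_id] = attr.subject_region_scores(m)
    return np.stack([by_id[s.subject_id] for s in cohort])
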
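"""End-to-end orchestration: one config in, one report bundle out.

``run_pipeline`` chains the stages — load or simulate a cohort, quality
control, imputation, edge-wise regression, inference matrix (negative
direction by default), dense-subnetwork extraction, max-statistic
permutation p-values, predefined-network mapping with hub screening, and
mediation/cognition models — and returns a JSON-serializable report.  A
single master seed is fanned out deterministically to every stochastic
stage, so identical configs give identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import yaml

from . import io as nio
from .core import SubjectTable, impute_missing, qc_filter
from .extract import DEFAULT_LAMBDA, extract_subnetworks
from .mapping import identify_hubs, map_to_predefined, replication_overlap
from .mediation import (
    cognitive_association,
    cognitive_score,
    fit_mediation,
    mean_subnetwork_rsfc,
)
from .permutation import attach_pvalues, build_null
from .regression import build_inference_matrix, fit_edges
from .simulate import CohortSpec, default_parcellation, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration problem; the message names the offending key path."""


def _require(cfg, path, typ=None):
    node = cfg
    walked = []
    for key in path.split("."):
        walked.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing config key: {'.'.join(walked)}")
        node = node[key]
    if typ is not None and not isinstance(node, typ):
        raise ConfigError(f"config key {path} must be of type {typ}")
    return node


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seeds(master: int) -> dict:
    names = ["synthetic", "permutation", "mediation", "cognition"]
    state = np.random.SeedSequence(int(master)).generate_state(len(names))
    return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def _load_cohort(cfg, seeds):
    data = _require(cfg, "data", dict)
    if "synthetic" in data:
        syn = dict(data["synthetic"])
        syn.setdefault("seed", seeds["synthetic"])
        try:
            spec = CohortSpec(**syn)
        except TypeError as exc:
            raise ConfigError(f"data.synthetic: {exc}") from exc
        stack, subjects, truth = generate_cohort(spec)
        return stack, subjects, truth
    conn = _require(cfg, "data.connectomes", dict)
    cov_path = _require(cfg, "data.covariates")
    fmt = conn.get("format", "hdf5")
    if fmt == "hdf5":
        stack = nio.read_hdf5(_require(cfg, "data.connectomes.path"))
    elif fmt == "long":
        stack = nio.read_long_edges(
            _require(cfg, "data.connectomes.path"),
            n_nodes=_require(cfg, "data.connectomes.n_nodes"),
        )
    elif fmt == "manifest":
        stack = nio.read_matrix_manifest(_require(cfg, "data.connectomes.path"))
    else:
        raise ConfigError("data.connectomes.format must be hdf5, long or manifest")
    subjects = nio.read_covariates(cov_path)
    return stack, subjects, None


def _subnetwork_record(sub, parc, W):
    mapping = map_to_predefined(sub.nodes, parc)
    return {
        "nodes": list(sub.nodes),
        "size": sub.size,
        "score": sub.score,
        "density": sub.density,
        "n_edges_sig": sub.n_edges_sig,
        "p_value": sub.p_value,
        "mapping": mapping["count"][mapping["count"] > 0].to_dict(),
        "hubs": identify_hubs(W, sub.nodes) if sub.size >= 2 else [],
    }


def run_pipeline(config, output_dir: str | None = None) -> dict:
    """Run the full analysis described by ``config`` (path, or dict).

    Returns the report dict; when ``output_dir`` (or ``config["output_dir"]``)
    is set, also writes ``report.json`` plus per-stage artifacts there.
    """
    cfg = load_config(config)
    master_seed = int(cfg.get("seed", 0))
    seeds = _stage_seeds(master_seed)
    output_dir = output_dir or cfg.get("output_dir")

    stack, subjects, truth = _load_cohort(cfg, seeds)
    subjects.check_aligned(stack)

    parc_path = cfg.get("parcellation")
    parc = nio.read_parcellation(parc_path) if parc_path else default_parcellation(stack.n_nodes)
    if parc.n_nodes != stack.n_nodes:
        raise ConfigError("parcellation size does not match the connectomes")

    qc_cfg = cfg.get("qc", {})
    try:
        filtered = qc_filter(
            stack,
            max_missing_ratio=qc_cfg.get("max_missing_ratio", 0.1),
            variation_bounds=tuple(qc_cfg.get("variation_bounds", (0.01, 2.0))),
        )
    except ValueError as exc:
        raise type(exc)(f"stage qc: {exc}") from exc
    keep = [stack.subject_ids.index(s) for s in filtered.subject_ids]
    subjects = subjects.subset(np.asarray(keep))
    stack = impute_missing(filtered)

    reg_cfg = cfg.get("regression", {})
    fits = fit_edges(
        stack,
        subjects,
        include_quadratic=reg_cfg.get("include_quadratic", "never"),
        alpha=reg_cfg.get("alpha", 0.05),
        r2_min=reg_cfg.get("r2_min", 0.01),
    )
    direction = reg_cfg.get("direction", "negative")
    W = build_inference_matrix(fits, direction=direction, w_max=reg_cfg.get("w_max", 50.0))

    ext_cfg = cfg.get("extraction", {})
    lam = ext_cfg.get("lam")
    lam = DEFAULT_LAMBDA if lam is None else float(lam)
    min_size = ext_cfg.get("min_size", 5)
    max_sub = ext_cfg.get("max_subnetworks", 10)
    result = extract_subnetworks(W, lam=lam, min_size=min_size, max_subnetworks=max_sub)

    perm_cfg = cfg.get("permutation", {})
    M = perm_cfg.get("M", 1000)
    null = build_null(
        stack,
        subjects,
        M=M,
        seed=seeds["permutation"],
        direction=direction,
        lam=lam,
        min_size=min_size,
        max_subnetworks=max_sub,
        include_quadratic=bool(fits.used_quadratic)
        if not isinstance(fits.used_quadratic, np.ndarray)
        else False,
        scheme=perm_cfg.get("scheme", "draper-stoneman"),
    )
    attach_pvalues(result, null)

    med_cfg = cfg.get("mediation", {})
    mediation_report = {}
    cognition_report = {}
    if med_cfg.get("enabled", True) and len(result) > 0:
        n_boot = med_cfg.get("n_boot", 500)
        has_cog = all(c in subjects.df.columns for c in SubjectTable.COGNITIVE)
        if has_cog:
            score, explained = cognitive_score(
                subjects.cognitive_battery, seed=seeds["cognition"]
            )
            cognition_report["pc1_explained_variance"] = explained
        for rank, sub in enumerate(result, start=1):
            mfc = mean_subnetwork_rsfc(stack, sub.nodes)
            entry = {}
            for med_name, col in (("fa", "fa"), ("wmh", "log_wmh")):
                if col not in subjects.df.columns:
                    continue
                res = fit_mediation(
                    subjects.age,
                    subjects.df[col].to_numpy(dtype=float),
                    mfc,
                    sex=subjects.sex,
                    n_boot=n_boot,
                    seed=seeds["mediation"] + rank,
                )
                entry[med_name] = {
                    "a": res.a,
                    "b": res.b,
                    "c_prime": res.c_prime,
                    "indirect": res.indirect,
                    "total": res.total,
                    "prop_mediated": res.prop_mediated,
                    "prop_mediated_pct": res.prop_mediated_pct,
                    "ci_prop": list(res.ci_prop),
                    "p_indirect": res.p_indirect,
                }
            mediation_report[f"subnetwork_{rank}"] = entry
            if has_cog:
                cognition_report[f"subnetwork_{rank}"] = cognitive_association(
                    score, mfc, subjects.age
                )

    report = {
        "config_hash": _config_hash(cfg),
        "seed": master_seed,
        "stage_seeds": seeds,
        "n_nodes": stack.n_nodes,
        "n_subjects": stack.n_subjects,
        "direction": direction,
        "lambda": lam,
        "permutations": M,
        "subnetworks": [_subnetwork_record(s, parc, W) for s in result],
        "mediation": mediation_report,
        "cognition": cognition_report,
    }
    if truth is not None:
        report["ground_truth"] = truth

    if output_dir:
        _write_bundle(output_dir, report, W, result, null, parc)
    return report


def _write_bundle(output_dir, report, W, result, null, parc):
    os.makedirs(output_dir, exist_ok=True)
    with open(os.path.join(output_dir, "report.json"), "w") as f:
        json.dump(report, f, indent=2, default=float)
    np.savetxt(os.path.join(output_dir, "inference_matrix.csv"), W.w, delimiter=",")
    np.savetxt(os.path.join(output_dir, "null_T.txt"), null.T_values)
    with open(os.path.join(output_dir, "null_meta.json"), "w") as f:
        json.dump(
            {"M": null.M, "seed": null.seed, "scheme": null.scheme,
             "config_hash": report["config_hash"]},
            f,
            indent=2,
        )
    rows = []
    net_of = parc.df.set_index("node_id")
    for rank, sub in enumerate(result, start=1):
        for v in sub.nodes:
            rows.append(
                {
                    "rank": rank,
                    "node_id": v,
                    "label": net_of.loc[v, "label"],
                    "network": net_of.loc[v, "network"],
                }
            )
    import pandas as pd

    pd.DataFrame(rows, columns=["rank", "node_id", "label", "network"]).to_csv(
        os.path.join(output_dir, "subnetworks.csv"), index=False
    )
    logger.info("report bundle written to %s", output_dir)


def compare_cohorts(report_a, report_b) -> dict:
    """Replication summary between two pipeline reports (dicts or JSON paths).

    Subnetworks are compared per rank: node overlap, Jaccard index, and the
    predefined-network tallies both cohorts share.
    """
    a = report_a if isinstance(report_a, dict) else json.load(open(report_a))
    b = report_b if isinstance(report_b, dict) else json.load(open(report_b))
    if a["n_nodes"] != b["n_nodes"]:
        raise ValueError(
            f"parcellation mismatch: {a['n_nodes']} vs {b['n_nodes']} nodes"
        )
    per_rank = []
    for rank, (sa, sb) in enumerate(zip(a["subnetworks"], b["subnetworks"]), start=1):
        overlap, count, jac = replication_overlap(sa["nodes"], sb["nodes"])
        shared = {
            k: min(sa["mapping"].get(k, 0), sb["mapping"].get(k, 0))
            for k in set(sa["mapping"]) | set(sb["mapping"])
        }
        per_rank.append(
            {
                "rank": rank,
                "size_a": sa["size"],
                "size_b": sb["size"],
                "overlap": count,
                "jaccard": jac,
                "overlap_nodes": overlap,
                "shared_network_tallies": shared,
            }
        )
    return {"n_nodes": a["n_nodes"], "per_rank": per_rank}
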
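"""End-to-end orchestration: simulate → cluster → grn → prune → signature.

``run_pipeline`` executes the five stages on one configuration, writes
every intermediate artifact as plain text under the output directory, and
records a manifest (parameters, seeds, SHA-256 of each output) so a rerun
with the same configuration is verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from onoffgrn import io as oio
from onoffgrn.clustering import (
    average_replicates,
    fuzzy_cmeans,
    log_transform,
    match_clusters,
    overlap_genes,
    znormalize,
)
from onoffgrn.direct import hive_quadrant_stats, prune_direct, tf_to_isg_matrix
from onoffgrn.grn import infer_network, rank_regulators
from onoffgrn.signature import extract_fast_onoff, score_signature, write_gmt
from onoffgrn.synthetic import SimConfig, simulate_annotations, simulate_timecourse

log = logging.getLogger("onoffgrn.pipeline")

STAGES = ("simulate", "cluster", "grn", "prune", "signature")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},  # SimConfig overrides
    "cluster": {"k": 6, "r_min": 0.8},
    "grn": {"n_trees": 100, "k_mode": "sqrt"},
    "prune": {"up": 400, "down": 300},
    "signature": {"k": 2, "model": "AB1", "quantile": 0.9},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Run all five stages; returns (and writes) the manifest dict."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "stages": []}
    outputs: dict[str, Path] = {}

    def record(stage: str, params: dict, files: dict[str, Path], t0: float) -> None:
        log.info("stage %s done in %.2fs (%s)", stage, time.perf_counter() - t0, params)
        manifest["stages"].append(
            {"name": stage, "params": params, "outputs": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for k, p in files.items()}}
        )
        outputs.update(files)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs.setdefault("seed", cfg["seed"])
    try:
        sim_cfg = SimConfig(**sim_kwargs)
        matrix, meta, truth = simulate_timecourse(sim_cfg)
        tss, tfbs = simulate_annotations(truth, seed=sim_cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    files = {k: out / n for k, n in [
        ("matrix", "matrix.tsv"), ("meta", "meta.tsv"), ("tss", "tss.bed"),
        ("tfbs", "tfbs.bed"), ("isg_sets", "isg_sets.gmt"), ("truth", "truth.json")]}
    oio.write_matrix(matrix, files["matrix"])
    meta.to_csv(files["meta"], sep="\t", index=False)
    oio.write_tss_bed(tss, files["tss"])
    oio.write_tfbs_bed(tfbs, files["tfbs"])
    write_gmt(truth.isg_sets, files["isg_sets"])
    truth_dict = dataclasses.asdict(truth)
    truth_dict["true_edges"] = sorted(truth.true_edges)
    truth_dict["direct_edges"] = sorted(truth.direct_edges)
    truth_dict["edge_weights"] = {f"{r}->{t}": w for (r, t), w in sorted(truth.edge_weights.items())}
    files["truth"].write_text(json.dumps(truth_dict, default=_json_default, sort_keys=True, indent=1))
    record("simulate", dataclasses.asdict(sim_cfg), files, t0)

    # --- cluster ------------------------------------------------------
    t0 = time.perf_counter()
    ck = cfg["cluster"]
    clusterings = {}
    responder_profiles = {}
    files = {}
    try:
        for model in sim_cfg.models:
            prof = average_replicates(matrix, meta, model, "responder")
            responder_profiles[model] = prof
            fc = fuzzy_cmeans(znormalize(log_transform(prof)), k=ck["k"], seed=cfg["seed"])
            clusterings[model] = fc
            files[f"membership_{model}"] = out / f"membership_{model}.tsv"
            files[f"centroids_{model}"] = out / f"centroids_{model}.tsv"
            fc.membership.to_csv(files[f"membership_{model}"], sep="\t", index_label="gene")
            fc.centroids.to_csv(files[f"centroids_{model}"], sep="\t", index_label="cluster")
        ma, mb = sim_cfg.models[0], sim_cfg.models[1]
        matches = match_clusters(clusterings[ma], clusterings[mb], r_min=ck["r_min"])
        mrows = []
        for mch in matches:
            ov = overlap_genes(clusterings[ma], mch.cluster_a, clusterings[mb], mch.cluster_b)
            mrows.append({"cluster_a": mch.cluster_a, "cluster_b": mch.cluster_b,
                          "pearson_r": mch.pearson_r, "n_overlap": len(ov),
                          "overlap_genes": ",".join(sorted(ov))})
        files["matches"] = out / "cluster_matches.tsv"
        pd.DataFrame(mrows, columns=["cluster_a", "cluster_b", "pearson_r", "n_overlap", "overlap_genes"]).to_csv(
            files["matches"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage cluster failed: {exc}") from exc
    record("cluster", ck, files, t0)

    # --- grn ----------------------------------------------------------
    t0 = time.perf_counter()
    gk = cfg["grn"]
    networks = {}
    files = {}
    try:
        for model in sim_cfg.models:
            ids = meta.loc[(meta["model"] == model) & (meta["response"] == "responder"), "sample_id"]
            net = infer_network(
                matrix.values[list(ids)], regulators=list(truth.tfs),
                n_trees=gk["n_trees"], k_mode=gk["k_mode"], seed=cfg["seed"],
            )
            networks[model] = net
            files[f"edges_{model}"] = out / f"edges_{model}.tsv"
            net.edges.to_csv(files[f"edges_{model}"], sep="\t", index=False)
            files[f"ranking_{model}"] = out / f"ranking_{model}.tsv"
            rank_regulators(net, top_n=min(100, len(truth.tfs))).to_csv(files[f"ranking_{model}"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage grn failed: {exc}") from exc
    record("grn", gk, files, t0)

    # --- prune --------------------------------------------------------
    t0 = time.perf_counter()
    pk = cfg["prune"]
    directs = {}
    files = {}
    try:
        for model in sim_cfg.models:
            d = prune_direct(
                networks[model], tss, tfbs, de_genes=truth.de_genes, tf_list=truth.tfs,
                up=pk["up"], down=pk["down"], ifn_tfs=truth.ifn_tfs,
            )
            directs[model] = d
            files[f"direct_edges_{model}"] = out / f"direct_edges_{model}.tsv"
            d.edges.to_csv(files[f"direct_edges_{model}"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage prune failed: {exc}") from exc
    record("prune", pk, files, t0)

    # --- signature ----------------------------------------------------
    t0 = time.perf_counter()
    sk = cfg["signature"]
    files = {}
    try:
        sig_model = sk["model"]
        sig = extract_fast_onoff(
            responder_profiles[sig_model],
            truth.isg_sets["IFN_ALPHA_BETA"], truth.isg_sets["IFN_GAMMA"],
            k=sk["k"], seed=cfg["seed"],
        )
        files["signature"] = out / "signature.tsv"
        pd.DataFrame(
            {"gene": sorted(sig.classes), "class": [sig.classes[g] for g in sorted(sig.classes)],
             "fast": [int(sig.fast_flag[g]) for g in sorted(sig.classes)]}
        ).to_csv(files["signature"], sep="\t", index=False)

        scores = score_signature(matrix, sorted(sig.fast_genes))
        files["scores"] = out / "signature_scores.tsv"
        scores.rename_axis("sample_id").to_csv(files["scores"], sep="\t")

        hive = {}
        for model in sim_cfg.models:
            d = directs[model]
            d.node_class = {  # fast flags are known only after this stage
                g: ("fast_isg" if cls == "other" and g in sig.fast_genes else cls)
                for g, cls in d.node_class.items()
            }
            hive[model] = hive_quadrant_stats(d, quantile=sk["quantile"])
            mat = tf_to_isg_matrix(d, sorted(truth.ifn_tfs), sorted(sig.fast_genes))
            files[f"tf_to_isg_{model}"] = out / f"tf_to_isg_{model}.tsv"
            mat.to_csv(files[f"tf_to_isg_{model}"], sep="\t")

        derived = sorted(sig.fast_genes)
        truth_fast = set(truth.fast_isg_genes)
        jaccard = len(set(derived) & truth_fast) / len(set(derived) | truth_fast)
        report = {"fast_genes": derived, "n_fast": len(derived),
                  "jaccard_fast_vs_truth": jaccard, "hive": hive}
        files["report"] = out / "report.json"
        files["report"].write_text(json.dumps(report, default=_json_default, sort_keys=True, indent=1))
    except Exception as exc:
        raise RuntimeError(f"stage signature failed: {exc}") from exc
    record("signature", sk, files, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, default=_json_default, sort_keys=True, indent=1))
    return manifest
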
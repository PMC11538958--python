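"""End-to-end orchestration of the repertoire-characterization pipeline.

``run_pipeline`` executes the stages in order — synthesis (or ingestion
of an existing bundle directory), spectrograms, auto-encoder embedding,
2-D projection, density clustering, optional review script, repertoire
finalization, contour features, cross-dataset statistics and the
classification tree — writing each stage's outputs into a run directory
as plain CSV/JSON so every report figure is recomputable from files
alone.  A single global seed fans out to per-stage seeds by fixed
offsets; rerunning with an identical config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from pilotcalls import audio_io, cart, cluster, embed, features as feat, spectro, stats, synthcalls
from pilotcalls.contour import read_contours


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run (serialized to the run log)."""

    seed: int = 0
    # synthesis (used when no input bundle is given)
    calls_per_type: int = 30
    snr_db: float = 20.0
    freq_jitter_frac: float = 0.05
    time_jitter_frac: float = 0.05
    # spectrogram geometry
    window_s: float = 0.043
    overlap_frac: float = 0.8
    target_bins: int = 128
    target_frames: int = 128
    # auto-encoder
    ae_epochs: int = 50
    ae_lr: float = 1e-3
    ae_batch: int = 32
    ae_hidden: int = 256
    # 2-D projection
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    # clustering / catalogue
    min_cluster_size: int = cluster.DEFAULT_MIN_CLUSTER_SIZE
    min_occurrence: int = 3
    review_script: str = ""
    # feature thresholds
    gap_min_s: float = feat.GAP_MIN_S
    jump_frac: float = feat.JUMP_FRAC
    jump_max_dt_s: float = feat.JUMP_MAX_DT_S
    smooth_win_pts: int = feat.SMOOTH_WIN_PTS
    min_slope_hz_per_s: float = feat.MIN_SLOPE_HZ_PER_S
    # statistics / tree
    alpha: float = 0.05
    min_group_n: int = 2
    run_stats: bool = True
    run_tree: bool = True
    tree_max_depth: int = 10
    tree_min_leaf: int = 1


def _write_df(df: pd.DataFrame, path: str, floatfmt: str = "%.6f") -> None:
    df.to_csv(path, index=False, float_format=floatfmt)


def _ingest_bundles(bundle_dir: str, datasets) -> tuple[list, dict]:
    """Read WAV + label bundles back as per-call vocalizations."""
    vocs = []
    truth = {}
    for ds in datasets:
        rate, audio = audio_io.read_wav(os.path.join(bundle_dir, f"{ds}.wav"))
        events = audio_io.read_label_track(os.path.join(bundle_dir, f"{ds}_labels.txt"))
        events = audio_io.merge_events(events)
        vocs.extend(audio_io.extract_vocalizations(
            audio, rate, events, ds, source_file=f"{ds}.wav",
            call_ids=[e.label for e in events]))
        truth_path = os.path.join(bundle_dir, f"{ds}_truth.csv")
        if os.path.exists(truth_path):
            for _, row in pd.read_csv(truth_path).iterrows():
                truth[row["call_id"]] = row["type_id"]
    return vocs, truth


def run_pipeline(config: RunConfig, out_dir: str, bundle_dir: str | None = None) -> dict:
    """Run every stage and return the report dictionary.

    Without ``bundle_dir`` the default synthetic repertoire is rendered
    first (10 planted types, two datasets); with one, the WAV + label
    bundles found there are ingested instead.  All stage outputs and the
    final ``report.json`` land in ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- stage: synth / ingest -------------------------------------------
    if bundle_dir is None:
        bundle_dir = os.path.join(out_dir, "bundles")
        spec = synthcalls.default_synth_spec(seed=config.seed,
                                             calls_per_type=config.calls_per_type,
                                             snr_db=config.snr_db)
        spec.freq_jitter_frac = config.freq_jitter_frac
        spec.time_jitter_frac = config.time_jitter_frac
        bundles = synthcalls.render_dataset(spec, bundle_dir)
        datasets = list(bundles)
    else:
        datasets = sorted(p[:-4] for p in os.listdir(bundle_dir) if p.endswith(".wav"))
    vocs, truth = _ingest_bundles(bundle_dir, datasets)
    audio_io.write_manifest(vocs, os.path.join(out_dir, "manifest.csv"))
    ds_of = {v.call_id: v.dataset for v in vocs}

    # --- stage: spectrograms + prepared inputs ---------------------------
    target_shape = (config.target_bins, config.target_frames)
    specs = {v.call_id: spectro.compute_spectrogram(v, window_s=config.window_s,
                                                    overlap_frac=config.overlap_frac)
             for v in vocs}
    call_ids = [v.call_id for v in vocs]
    prepared = np.stack([spectro.prepare_input(specs[c], target_shape) for c in call_ids])
    np.savez_compressed(os.path.join(out_dir, "prepared_inputs.npz"),
                        call_ids=np.array(call_ids), inputs=prepared.astype(np.float32))

    # --- stage: auto-encoder embedding -----------------------------------
    ae = embed.train_autoencoder(prepared, embed.AutoencoderConfig(
        epochs=config.ae_epochs, lr=config.ae_lr, batch=config.ae_batch,
        seed=config.seed + 1, hidden=config.ae_hidden))
    emb = ae.encode(prepared)
    emb_df = pd.DataFrame(emb, columns=[f"e{i+1}" for i in range(emb.shape[1])])
    emb_df.insert(0, "call_id", call_ids)
    _write_df(emb_df, os.path.join(out_dir, "embeddings.csv"))
    with open(os.path.join(out_dir, "loss_history.json"), "w") as fh:
        json.dump(ae.loss_history, fh)
        fh.write("\n")

    # --- stage: 2-D projection -------------------------------------------
    proj = embed.project_2d(emb, embed.ProjectionConfig(
        n_neighbors=config.umap_neighbors, min_dist=config.umap_min_dist,
        seed=config.seed + 2))
    proj_df = pd.DataFrame({"call_id": call_ids, "x": proj[:, 0], "y": proj[:, 1]})
    _write_df(proj_df, os.path.join(out_dir, "projection.csv"))

    # --- stage: clustering + review + repertoire -------------------------
    assignments = cluster.run_hdbscan(proj_df, min_cluster_size=config.min_cluster_size)
    audit: list = []
    if config.review_script.strip():
        assignments, audit = cluster.apply_review(assignments, config.review_script)
    _write_df(pd.DataFrame({"call_id": list(assignments),
                            "cluster_label": [assignments[c] for c in assignments]}),
              os.path.join(out_dir, "assignments.csv"))
    rep = cluster.finalize_repertoire(assignments, ds_of, min_occurrence=config.min_occurrence)
    rep.occurrence_matrix().to_csv(os.path.join(out_dir, "occurrence_matrix.csv"))
    with open(os.path.join(out_dir, "repertoire.json"), "w") as fh:
        json.dump({"n_detected": rep.n_detected, "n_classified": rep.n_classified,
                   "types": {t.type_label: {"occurrence": t.occurrence,
                                            "per_dataset": t.per_dataset,
                                            "call_ids": t.call_ids}
                             for t in rep.types}}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- stage: contour features -----------------------------------------
    contours = []
    for ds in datasets:
        contours.extend(read_contours(os.path.join(bundle_dir, f"{ds}_contours.csv")))
    fts = [feat.compute_features(
        c, specs.get(c.call_id), gap_min_s=config.gap_min_s, jump_frac=config.jump_frac,
        jump_max_dt_s=config.jump_max_dt_s, smooth_win_pts=config.smooth_win_pts,
        min_slope_hz_per_s=config.min_slope_hz_per_s) for c in contours]
    ft_df = feat.features_table(fts)
    _write_df(ft_df, os.path.join(out_dir, "features.csv"))

    # --- stage: statistics ------------------------------------------------
    type_of = {cid: t.type_label for t in rep.types for cid in t.call_ids}
    ft_df["type"] = [type_of.get(c, "") for c in ft_df["call_id"]]
    typed = ft_df[ft_df["type"] != ""]
    type_table = typed.groupby("type")[["f_min_hz", "f_mean_hz", "f_max_hz", "dur_s"]].mean()
    stats_report: dict = {}
    if config.run_stats and len(rep.types) >= 3:
        excl, eligible = stats.label_exclusivity(rep, min_group_n=config.min_group_n)
        stats_report["exclusivity"] = excl
        stats_report["eligible_datasets"] = eligible
        summary = stats.summarize_types(type_table.reset_index())
        stats_report["summary"] = summary["global"]
        corr = stats.frequency_correlations(type_table)
        stats_report["correlations"] = {f"{a}-{b}": {"rho": r, "p": p}
                                        for (a, b), (r, p) in corr.items()}
        cfg_s = stats.StatsConfig(alpha=config.alpha, min_group_n=config.min_group_n)
        for col, label in (("dur_s", "duration"), ("f_mean_hz", "mean_frequency")):
            groups = {}
            for t, row in type_table.iterrows():
                g = excl.get(t, "mixed")
                if g in eligible:
                    groups.setdefault(g, []).append(float(row[col]))
            groups = {g: v for g, v in groups.items() if len(v) >= 3}
            if len(groups) >= 2:
                res = stats.gated_group_test(groups, cfg_s)
                stats_report[label] = {
                    "test": res.test_name, "statistic": res.statistic,
                    "p_value": res.p_value, "decision_path": res.decision_path,
                    "shapiro_w": res.shapiro_w, "shapiro_p": res.shapiro_p,
                }
            else:
                stats_report[label] = {"test": "skipped", "reason": "too few groups/values"}
        with open(os.path.join(out_dir, "stats.json"), "w") as fh:
            json.dump(stats_report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    # --- stage: classification tree --------------------------------------
    tree_report: dict = {}
    if config.run_tree and len(rep.types) >= 2:
        tree_in = typed[["dur_s", "bw_hz", "peak_hz", "range_ratio", "trend_ratio",
                         "n_inflections", "n_segments", "n_elements"]]
        tree = cart.fit_tree(tree_in, typed["type"],
                             cart.TreeConfig(max_depth=config.tree_max_depth,
                                             min_leaf=config.tree_min_leaf))
        preds = cart.classify_table(tree, tree_in)
        acc = float(np.mean([p == t for p, t in zip(preds, typed["type"])]))
        tree_report = {
            "training_accuracy": acc,
            "global_gini_all_nodes": cart.global_gini(tree, "all"),
            "global_gini_internal": cart.global_gini(tree, "internal") if not tree.is_leaf else None,
            "global_gini_leaves": cart.global_gini(tree, "leaves"),
            "n_nodes": sum(1 for _ in tree.nodes()),
        }
        cart.tree_to_json(tree, os.path.join(out_dir, "tree.json"))
        with open(os.path.join(out_dir, "tree.txt"), "w") as fh:
            fh.write(cart.render_tree(tree))

    # --- stage: report ----------------------------------------------------
    seg_counts = typed.groupby("type")["n_segments"].max()
    el_counts = typed.groupby("type")["n_elements"].max()
    shared = sum(1 for t in rep.types if len(t.per_dataset) > 1)
    report = report_summary(
        n_detected=rep.n_detected, n_classified=rep.n_classified,
        n_types=len(rep.types),
        n_types_multisegment=int((seg_counts > 1).sum()),
        n_types_multielement=int((el_counts > 1).sum()),
        n_types_shared=shared)
    report["element_histogram"] = el_counts.value_counts().sort_index().to_dict()
    report["segment_histogram"] = seg_counts.value_counts().sort_index().to_dict()
    report["stats"] = stats_report
    report["tree"] = tree_report
    report["review_audit"] = audit
    if truth:
        ari, _, n_noise = cluster.recovery_score(assignments, truth)
        kept_types = {type_of[c] for c in type_of}
        report["recovery"] = {"adjusted_rand_index": ari, "n_noise": n_noise,
                              "n_recovered_types": len(kept_types),
                              "n_true_types": len(set(truth.values()))}
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report


def report_summary(n_detected: int, n_classified: int, n_types: int,
                   n_types_multisegment: int, n_types_multielement: int,
                   n_types_shared: int) -> dict:
    """Catalogue-level report arithmetic.

    Percentages are rounded to the nearest integer for display, with the
    unrounded values retained alongside.
    """
    def pct(num, den):
        return None if den == 0 else 100.0 * num / den

    out = {
        "n_detected": n_detected,
        "n_classified": n_classified,
        "n_unclassified": n_detected - n_classified,
        "n_types": n_types,
        "percent_classified_exact": pct(n_classified, n_detected),
        "mean_occurrence_per_type": (n_classified / n_types) if n_types else None,
        "percent_multisegment_types_exact": pct(n_types_multisegment, n_types),
        "percent_multielement_types_exact": pct(n_types_multielement, n_types),
        "percent_shared_types_exact": pct(n_types_shared, n_types),
    }
    for key in list(out):
        if key.endswith("_exact") and out[key] is not None:
            out[key.replace("_exact", "")] = round(out[key])
    return out
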
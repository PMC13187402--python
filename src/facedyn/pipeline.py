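"""End-to-end pipeline orchestration with deterministic per-stage seeding.

The pipeline runs: simulate (or ingest) -> preprocess -> stratified split ->
NMF decomposition on the training matrix -> projection of the held-out test
matrix -> feature extraction -> train-only PCA -> classification ->
substate segmentation -> mixed-model statistics.  The train/test firewall
is structural: the spatial basis, feature scaler and PCA loadings are all
fitted on training trials only and merely applied to test trials.

Every stage writes its artifact (TSV/JSON) into the run directory, and all
stage seeds are derived by hashing (master seed, stage name), so adding a
stage never perturbs the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import decomposition as dec
from . import features as feat
from . import group_stats as gstats
from . import io_preprocess as iop
from . import substates as sub
from . import synthetic as syn

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "stage_seed", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "paths": {"out_dir": "facedyn_run"},
    "synthetic": {
        "k_true": 3, "n_aus": 18, "n_bins": 100, "n_frames": 240,
        "noise_sd": 0.05, "n_subjects": 8, "trials_per_cell": 2,
        "conditions": ["expression_only"],
    },
    "preprocessing": {"window": 3, "n_bins": 100, "confidence_threshold": 0.90},
    "decomposition": {"k_range": [2, 6], "n_runs": 10, "n_null": 3,
                      "block_len": 10},
    "features": {"catalog": feat.CATALOG_VERSION},
    "classification": {"frac": 0.8, "cv_folds": 5, "n_perm": 1000},
    "substates": {"c": 3, "window": 10, "stride": 5, "max_trials": 24},
    "seed": 0,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, from (master seed, stage)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %s", path)


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full synthetic-data pipeline; returns a results summary dict.

    All intermediate artifacts are written under the run directory; the
    summary is also saved as ``report.json``.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    master = int(cfg["seed"])
    out = Path(out_dir or cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    # ---- simulate -------------------------------------------------------
    sc = cfg["synthetic"]
    gt = syn.make_ground_truth(sc["k_true"], sc["n_aus"], sc["n_bins"],
                               seed=stage_seed(master, "simulate"),
                               noise_sd=sc["noise_sd"])
    trials = syn.make_dataset(gt, n_subjects=sc["n_subjects"],
                              trials_per_cell=sc["trials_per_cell"],
                              seed=stage_seed(master, "dataset"),
                              n_frames=sc["n_frames"],
                              conditions=tuple(sc["conditions"]))
    log.info("simulated %d trials", len(trials))

    # ---- preprocess -----------------------------------------------------
    pc = cfg["preprocessing"]
    trials = iop.filter_by_confidence(trials, pc["confidence_threshold"])
    binned = iop.preprocess_trials(trials, window=pc["window"],
                                   n_bins=pc["n_bins"])
    stacked = iop.stack_trials(binned, pc["n_bins"])

    # ---- split (before any fitting) -------------------------------------
    emotions = stacked.meta["emotion"].to_numpy()
    tr_idx, te_idx = clf.split_train_test(
        emotions, frac=cfg["classification"]["frac"],
        seed=stage_seed(master, "split"))
    train_ids = [stacked.trial_ids[i] for i in tr_idx]
    test_ids = [stacked.trial_ids[i] for i in te_idx]
    M_train = stacked.subset(train_ids)
    M_test = stacked.subset(test_ids) if test_ids else None
    json.dump({"train": train_ids, "test": test_ids},
              open(out / "split.json", "w"), indent=1)

    # ---- decompose on training data -------------------------------------
    dc = cfg["decomposition"]
    k_lo, k_hi = dc["k_range"]
    report = dec.select_k(M_train, range(k_lo, k_hi + 1), n_runs=dc["n_runs"],
                          n_null=dc["n_null"], block_len=dc["block_len"],
                          seed=stage_seed(master, "decompose"))
    k = report.chosen_k
    model = dec.nmf_fit(M_train, k, seed=stage_seed(master, "nmf"))
    _write_tsv(report.table, out / "k_selection.tsv")
    _write_tsv(pd.DataFrame(model.S, columns=[f"AU{a:02d}" for a in
                                              stacked.au_numbers]),
               out / "spatial_weights.tsv")

    # ---- project train + test -------------------------------------------
    T_train = dec.project(model, M_train)
    traj_train, _ = dec.trajectories(T_train, M_train)
    if M_test is not None:
        T_test = dec.project(model, M_test)
        traj_test, _ = dec.trajectories(T_test, M_test)
    else:
        traj_test = {}

    # ---- features + PCA (train statistics only) --------------------------
    table_train = feat.build_feature_table(traj_train)
    pca = feat.fit_feature_pca(table_train, n_components=k)
    scores_train = feat.apply_feature_pca(pca, table_train)
    table_test = feat.build_feature_table(traj_test) if traj_test else None
    scores_test = (feat.apply_feature_pca(pca, table_test)
                   if table_test is not None else None)
    _write_tsv(table_train.reset_index(), out / "features_train.tsv")

    # ---- classify --------------------------------------------------------
    meta_train = M_train.meta.set_index("trial_id").loc[train_ids]
    y_train = meta_train["emotion"].to_numpy()
    search = clf.train_classifier(scores_train, y_train,
                                  seed=stage_seed(master, "classify"),
                                  cv_folds=cfg["classification"]["cv_folds"])
    clf_report = None
    if scores_test is not None and len(test_ids):
        y_test = M_test.meta.set_index("trial_id").loc[test_ids][
            "emotion"].to_numpy()
        clf_report = clf.evaluate(search, scores_test, y_test,
                                  n_perm=cfg["classification"]["n_perm"],
                                  seed=stage_seed(master, "permute"))

    # ---- substates -------------------------------------------------------
    ss = cfg["substates"]
    sub_ids = train_ids[: ss["max_trials"]]
    dt = sc["n_frames"] / 30.0 / pc["n_bins"]  # seconds per bin at 30 fps
    kins = [sub.compute_kinematics(traj_train[t], dt=dt) for t in sub_ids]
    seqs = sub.segment_substates(kins, c=ss["c"], window=ss["window"],
                                 stride=ss["stride"],
                                 seed=stage_seed(master, "substates"))
    long_rows = []
    meta_idx = M_train.meta.set_index("trial_id")
    for tid, seq, kin in zip(sub_ids, seqs, kins):
        speeds = sub.substate_speed_summary(seq, kin)
        ent = sub.transition_entropy(seq.labels)
        m = meta_idx.loc[tid]
        for state, v in speeds.items():
            long_rows.append({"trial": tid, "subject": m["subject_id"],
                              "emotion": m["emotion"],
                              "condition": m["condition"], "substate": state,
                              "value": v, "entropy": ent})
    long = pd.DataFrame(long_rows)
    _write_tsv(long, out / "substate_summary.tsv")

    # ---- stats -----------------------------------------------------------
    lmm_summary = None
    if long["subject"].nunique() >= 2 and long["condition"].nunique() >= 2:
        model_lmm = gstats.fit_substate_lmm(long.dropna(subset=["value"]),
                                            response="speed")
        lmm_summary = {
            "random_structure": model_lmm.random_structure,
            "r2_marginal": model_lmm.r2_marginal,
            "r2_conditional": model_lmm.r2_conditional,
        }

    summary = {
        "n_trials": len(trials),
        "chosen_k": k,
        "k_table": report.table.to_dict("records"),
        "classifier": None if clf_report is None else {
            "accuracy": clf_report.accuracy,
            "balanced_accuracy": clf_report.balanced_accuracy,
            "kappa": clf_report.kappa,
            "no_information_rate": clf_report.no_information_rate,
            "p_binomial": clf_report.p_binomial,
            "p_permutation": clf_report.p_permutation,
        },
        "substate_mean_speed": {
            s: float(np.nanmean(long.loc[long["substate"] == s, "value"]))
            for s in sub.SUBSTATE_LABELS},
        "mean_entropy": float(long.groupby("trial")["entropy"].first().mean()),
        "lmm": lmm_summary,
        "seed": master,
    }
    json.dump(summary, open(out / "report.json", "w"), indent=1, default=float)
    log.info("pipeline complete; report at %s", out / "report.json")
    return summary
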
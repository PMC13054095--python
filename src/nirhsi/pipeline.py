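"""One-command orchestration of the full analysis workflow.

Stages: cohort (phantom generation or manifest load) -> preprocessing ->
autoencoder feature extraction -> consensus outlier detection and
strong-outlier removal -> LOOCV classification -> clustering scan and
stability -> visualizations. Every stage's effective parameters are
serialized into the run record together with artifact paths, SHA-256
checksums and wall times; identical config + seed reproduces identical
artifact checksums.

Randomness: one global seed is fanned out to named per-stage substreams
(``SeedSequence((seed, crc32(stage)))``) so stages can be rerun
independently yet reproducibly.

Feature handling inside LOOCV: ``feature_mode: global`` (default) trains
the autoencoder once, unsupervised, on the whole cohort — the study
procedure; ``per_fold`` refits it on each fold's training samples only,
trading a large constant factor for strict leakage-freedom.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as clu
from .classifier import (
    ClassifierConfig,
    attention_map,
    predict,
    train_classifier,
)
from .cube_io import HyperCube, preprocess, read_cube, read_manifest
from .errors import ConfigError
from .evaluation import CVResult, balanced_accuracy, class_metrics, loocv
from .features import (
    AutoencoderConfig,
    aggregate_features,
    encode_patches,
    extract_patches,
    features_table,
    train_autoencoder,
)
from .outliers import detect_outliers, remove_strong
from .phantom import PhantomConfig, generate_cohort

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "stage_seed",
    "extract_cohort_features",
    "loocv_with_feature_refit",
    "run_pipeline",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "nirhsi_run",
    "stages": {
        "outliers": True,
        "classification": True,
        "clustering": True,
        "viz": True,
    },
    "phantom": {},  # PhantomConfig fields; used when no manifest given
    "manifest": None,  # path to cohort CSV (overrides phantom)
    "preprocess": {"k_sd": 5.0, "scope": "cube"},
    "features": {
        "patch_size": 5,
        "stride": 2,
        "latent_dim": 128,
        "epochs": 20,
        "batch_size": 256,
        "learning_rate": 1e-3,
        "max_train_patches": 6000,
    },
    "outliers": {
        "z_max": 3.0,
        "fence_k": 1.5,
        "feature_fraction": 0.10,
        "alpha": 0.001,
        "contamination": 0.1,
        "n_neighbors": 20,
    },
    "classifier": {},  # ClassifierConfig fields
    "evaluation": {"feature_mode": "global"},
    "clustering": {"k_min": 2, "k_max": 10, "n_init": 10, "stability_runs": 20},
    "viz": {"bands": [2, 0, 1], "weights": [1.0, 0.8, 1.0], "map_clusters": 5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge YAML config (if any) and overrides onto the defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream seed: stable, independent per stage."""
    ss = np.random.SeedSequence((int(global_seed), zlib.crc32(stage.encode())))
    return int(ss.generate_state(1)[0] % (2**31))


def _pool_patches(
    patch_sets: list, max_total: int, seed: int
) -> np.ndarray:
    """Uniform random subsample of pooled patches for autoencoder training."""
    counts = np.array([len(p) for p in patch_sets])
    total = int(counts.sum())
    all_p = np.concatenate([p.patches for p in patch_sets])
    if total <= max_total:
        return all_p
    idx = np.random.default_rng(seed).choice(total, size=max_total, replace=False)
    return all_p[np.sort(idx)]


def extract_cohort_features(
    cubes: list[HyperCube],
    patch_size: int = 5,
    stride: int = 2,
    latent_dim: int = 128,
    epochs: int = 20,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
    max_train_patches: int = 6000,
    seed: int = 0,
):
    """Patch -> autoencoder -> embed -> aggregate, for a whole cohort.

    Returns (features DataFrame, trained EncoderModel, per-sample
    EmbeddingSets).
    """
    patch_sets = [extract_patches(c, patch_size, stride) for c in cubes]
    pool = _pool_patches(patch_sets, max_train_patches, seed)
    ae_cfg = AutoencoderConfig(
        latent_dim=latent_dim,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        seed=seed,
    )
    model = train_autoencoder(pool, ae_cfg)
    embeddings = [encode_patches(model, p) for p in patch_sets]
    feats = features_table([aggregate_features(e) for e in embeddings])
    return feats, model, embeddings


def loocv_with_feature_refit(
    cubes: list[HyperCube],
    labels: np.ndarray,
    clf_config: ClassifierConfig,
    feature_kwargs: dict,
    seed: int = 0,
) -> CVResult:
    """Strictly leakage-free LOOCV: refit the autoencoder on each fold.

    Fold i trains the autoencoder and classifier on the n - 1 training
    cubes only, then featurizes and predicts the held-out cube. Costs n
    autoencoder fits; intended for small cohorts.
    """
    y = np.asarray(labels, dtype=int)
    n = len(cubes)
    records = []
    for i in range(n):
        train_cubes = [c for j, c in enumerate(cubes) if j != i]
        feats_tr, model, _ = extract_cohort_features(
            train_cubes, seed=seed + i, **feature_kwargs
        )
        ps = extract_patches(
            cubes[i], feature_kwargs.get("patch_size", 5), feature_kwargs.get("stride", 2)
        )
        feat_i = aggregate_features(encode_patches(model, ps)).vector[None, :]
        clf = train_classifier(
            feats_tr.to_numpy(), y[np.arange(n) != i], replace(clf_config, seed=seed + i)
        )
        pred, proba = predict(clf, feat_i)
        records.append(
            {
                "sample_id": cubes[i].sample_id,
                "y_true": int(y[i]),
                "y_pred": int(pred[0]),
                "proba_1": float(proba[0, 1]),
                "degenerate": False,
            }
        )
    folds = pd.DataFrame(records)
    ba = balanced_accuracy(folds["y_true"], folds["y_pred"])
    return CVResult(
        folds=folds,
        balanced_accuracy=ba,
        metrics=class_metrics(folds["y_true"], folds["y_pred"]),
        config=clf_config.to_dict(),
        seed=seed,
        audit=[{"feature_mode": "per_fold"}],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(cfg: dict) -> tuple[list[HyperCube], np.ndarray, dict]:
    if cfg.get("manifest"):
        manifest = read_manifest(cfg["manifest"])
        base = Path(cfg["manifest"]).parent
        cubes = []
        labels = []
        for rec in manifest:
            p = Path(rec["path"])
            cube = read_cube(p if p.is_absolute() else base / p)
            cube.sample_id = rec["sample_id"]
            cube.label = rec["label"]
            cubes.append(cube)
            labels.append(rec["label"] if rec["label"] is not None else -1)
        return cubes, np.asarray(labels, dtype=int), {"source": "manifest"}
    ph_fields = dict(cfg.get("phantom", {}))
    ph_fields.setdefault("seed", stage_seed(cfg["seed"], "phantom"))
    ph_cfg = PhantomConfig(**ph_fields)
    cubes, labels = generate_cohort(ph_cfg)
    truth = {
        "source": "phantom",
        "params": ph_cfg.to_dict(),
        "planted_outliers": [c.sample_id for c in cubes if c.meta.get("is_outlier")],
    }
    return cubes, labels, truth


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the full workflow; returns (and writes) the run record."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else _merge(DEFAULT_CONFIG, config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    record: dict = {"config": cfg, "stages": {}, "artifacts": {}}
    stages_on = cfg["stages"]

    def finish_stage(name: str, t0: float, **info) -> None:
        record["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}

    def add_artifact(name: str, path: Path) -> None:
        record["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # -- cohort ---------------------------------------------------------
        t0 = time.time()
        cubes, labels, cohort_info = _load_cohort(cfg)
        finish_stage("cohort", t0, n_samples=len(cubes), **cohort_info)

        # -- preprocess -----------------------------------------------------
        t0 = time.time()
        pp = cfg["preprocess"]
        cubes = [preprocess(c, k_sd=pp["k_sd"], scope=pp["scope"]) for c in cubes]
        finish_stage("preprocess", t0, **pp)

        # -- features -------------------------------------------------------
        t0 = time.time()
        f_cfg = dict(cfg["features"])
        feats, model, embeddings = extract_cohort_features(
            cubes, seed=stage_seed(cfg["seed"], "features"), **f_cfg
        )
        fpath = out / "features.csv"
        feats.to_csv(fpath)
        add_artifact("features", fpath)
        finish_stage(
            "features",
            t0,
            **f_cfg,
            n_patches_per_sample=len(embeddings[0]),
            final_recon_loss=model.loss_history[-1],
        )

        # -- outliers -------------------------------------------------------
        survivors = list(range(len(cubes)))
        if stages_on.get("outliers", True):
            t0 = time.time()
            o_cfg = dict(cfg["outliers"])
            report = detect_outliers(
                feats, seed=stage_seed(cfg["seed"], "outliers"), **o_cfg
            )
            rpath = report.save(out / "outlier_report.json")
            add_artifact("outlier_report", rpath)
            kept = remove_strong(cubes, report)
            kept_ids = {c.sample_id for c in kept}
            survivors = [i for i, c in enumerate(cubes) if c.sample_id in kept_ids]
            finish_stage(
                "outliers",
                t0,
                strong=report.strong_ids,
                moderate=report.moderate_ids,
                n_survivors=len(survivors),
            )
        cubes_s = [cubes[i] for i in survivors]
        feats_s = feats.iloc[survivors]
        labels_s = labels[survivors]
        emb_s = [embeddings[i] for i in survivors]

        # -- classification -------------------------------------------------
        if stages_on.get("classification", True):
            t0 = time.time()
            clf_config = ClassifierConfig(
                **{**cfg["classifier"], "seed": stage_seed(cfg["seed"], "classifier")}
            )
            mode = cfg["evaluation"]["feature_mode"]
            if mode == "per_fold":
                cv = loocv_with_feature_refit(
                    cubes_s, labels_s, clf_config, f_cfg, seed=stage_seed(cfg["seed"], "evaluation")
                )
            elif mode == "global":
                cv = loocv(feats_s, labels_s, clf_config)
            else:
                raise ConfigError(f"unknown feature_mode {mode!r}")
            cvpath = cv.save(out / "cv_result.json")
            add_artifact("cv_result", cvpath)
            cv.folds.to_csv(out / "cv_folds.csv", index=False)
            add_artifact("cv_folds", out / "cv_folds.csv")
            finish_stage(
                "classification",
                t0,
                feature_mode=mode,
                balanced_accuracy=cv.balanced_accuracy,
                n_folds=len(cv.folds),
            )

        # -- clustering -----------------------------------------------------
        if stages_on.get("clustering", True):
            t0 = time.time()
            c_cfg = cfg["clustering"]
            seed_c = stage_seed(cfg["seed"], "clustering")
            scan = clu.kmeans_scan(
                feats_s.to_numpy(),
                range(c_cfg["k_min"], min(c_cfg["k_max"], len(feats_s) - 1) + 1),
                n_init=c_cfg["n_init"],
                seed=seed_c,
            )
            sils = [r.silhouette for r in scan]
            best_k = scan[int(np.nanargmax(sils))].k
            stability, _ = clu.cluster_stability(
                feats_s.to_numpy(), best_k, n_runs=c_cfg["stability_runs"], seed=seed_c
            )
            two = next((r for r in scan if r.k == 2), None)
            ari_labels = (
                clu.adjusted_rand_index(two.assignments, labels_s) if two is not None else None
            )
            scan_out = {
                "results": [
                    {
                        "k": r.k,
                        "inertia": r.inertia,
                        "silhouette": r.silhouette,
                        "assignments": r.assignments.tolist(),
                    }
                    for r in scan
                ],
                "best_k": int(best_k),
                "stability_mean_ari": stability,
                "ari_vs_labels_k2": ari_labels,
            }
            spath = out / "cluster_scan.json"
            spath.write_text(json.dumps(scan_out, indent=2, sort_keys=True))
            add_artifact("cluster_scan", spath)
            finish_stage(
                "clustering", t0, best_k=int(best_k), stability_mean_ari=stability,
                ari_vs_labels_k2=ari_labels,
            )

        # -- visualizations -------------------------------------------------
        if stages_on.get("viz", True):
            t0 = time.time()
            v = cfg["viz"]
            cube0 = cubes_s[0]
            fc = clu.false_color(cube0, tuple(v["bands"]), tuple(v["weights"]))
            clu.save_image(fc, out / "false_color.png")
            add_artifact("false_color", out / "false_color.png")
            cmap = clu.pixel_cluster_map(
                cube0,
                model,
                k=v["map_clusters"],
                seed=stage_seed(cfg["seed"], "viz"),
                patch_size=f_cfg["patch_size"],
                stride=f_cfg["stride"],
            )
            clu.save_image(cmap, out / "cluster_map.tiff")
            add_artifact("cluster_map", out / "cluster_map.tiff")
            if stages_on.get("classification", True):
                attn_cfg = ClassifierConfig(
                    **{
                        **cfg["classifier"],
                        "use_attention": True,
                        "seed": stage_seed(cfg["seed"], "attention"),
                    }
                )
                attn_model = train_classifier(feats_s, labels_s, attn_cfg)
                amap = attention_map(attn_model, emb_s[0], cube0.data.shape[:2])
                clu.save_image(amap, out / "attention_map.png")
                add_artifact("attention_map", out / "attention_map.png")
            finish_stage("viz", t0, sample=cube0.sample_id)
    except Exception as exc:  # partial-run record names the failing stage
        record["failed_stage"] = {
            "after_stages": list(record["stages"]),
            "error": f"{type(exc).__name__}: {exc}",
        }
        (out / "run_record.json").write_text(
            json.dumps(record, indent=2, sort_keys=True, default=str)
        )
        raise

    rec_path = out / "run_record.json"
    rec_path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return record
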
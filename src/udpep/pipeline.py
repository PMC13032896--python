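"""End-to-end orchestration: design -> simulate -> train -> attribute.

Every stage writes plain-text artifacts into the run directory and the
manifest records a checksum, the seeds used, and wall-clock timings, so any
stage can be re-run and compared in isolation.  Seeds for each randomised
stage are derived from the global seed by fixed offsets (design +0,
simulate +1, split +2, train +3, attribute +4).
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .errors import UdpepError
from .modeling import BackendSpec, SplitSpec, evaluate, make_splits, tune_and_train
from .peptide_space import SpaceSpec, encode_matrix
from .synthetic_data import PlantedModel, generate_dataset
from .uniform_design import SoatConfig, design_to_peptides, save_design, soat_optimize

__all__ = ["run_pipeline"]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _planted_for(cfg: RunConfig) -> PlantedModel:
    if cfg.simulate.preset == "null":
        base = PlantedModel.null()
    elif cfg.simulate.preset == "noisy":
        base = PlantedModel(noise_sd=0.5)
    else:
        base = PlantedModel()
    if cfg.simulate.noise_sd is not None:
        from dataclasses import replace

        base = replace(base, noise_sd=cfg.simulate.noise_sd)
    return base


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    On stage failure the manifest (with the failure point and partial
    artifacts) is still written, and the exception re-raised.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.normalized(),
        "config_hash": config_hash(cfg),
        "artifacts": {},
        "timings_s": {},
        "seeds": {},
        "status": "running",
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _checksum(path),
        }

    def save_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "design"
    try:
        # ---- design
        t0 = time.perf_counter()
        seed_design = cfg.seed
        manifest["seeds"]["design"] = seed_design
        soat = SoatConfig(
            outer_loops=cfg.design.outer_loops,
            inner_loops=cfg.design.inner_loops,
            initial_threshold_quantile=cfg.design.initial_threshold_quantile,
            threshold_decay=cfg.design.threshold_decay,
            seed=seed_design,
        )
        design = soat_optimize(cfg.design.n, cfg.design.k, 20, soat)
        design_path = out / "design.csv"
        save_design(design, design_path, soat)
        record("design", design_path)
        record("design_meta", design_path.with_suffix(".json"))
        manifest["timings_s"]["design"] = round(time.perf_counter() - t0, 3)

        # ---- simulate
        stage = "simulate"
        t0 = time.perf_counter()
        seed_sim = cfg.seed + 1
        manifest["seeds"]["simulate"] = seed_sim
        planted = _planted_for(cfg)
        seqs = design_to_peptides(design)
        dataset = generate_dataset(seqs, planted, seed=seed_sim)
        data_path = out / "synthetic.csv"
        dataset.to_csv(data_path, index=False)
        record("synthetic", data_path)
        manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)

        # ---- train
        stage = "train"
        t0 = time.perf_counter()
        seed_split = cfg.seed + 2
        seed_train = cfg.seed + 3
        manifest["seeds"].update({"split": seed_split, "train": seed_train})
        space = SpaceSpec(cfg.design.k)
        splits = make_splits(
            space,
            seqs,
            SplitSpec(
                train_fraction=cfg.train.train_fraction,
                fixed_test_size=cfg.train.fixed_test_size,
                seed=seed_split,
            ),
        )
        label_map = dict(zip(dataset["sequence"], dataset[cfg.train.property]))
        train_seqs = splits.sequences("train")
        val_seqs = splits.sequences("validation")
        X_tr = encode_matrix(train_seqs)
        y_tr = np.array([label_map[s] for s in train_seqs])
        test_seqs = splits.sequences("fixed_test")
        test_ds = generate_dataset(test_seqs, planted, seed=seed_sim + 10)
        metrics_rows = []
        for kind in cfg.train.backends:
            tuned = tune_and_train(
                X_tr,
                y_tr,
                BackendSpec(
                    kind=kind,
                    n_search=cfg.train.n_search,
                    cv_folds=cfg.train.cv_folds,
                    seed=seed_train,
                ),
            )
            for split_name, sseqs, ys in (
                ("validation", val_seqs, np.array([label_map[s] for s in val_seqs])),
                ("fixed_test", test_seqs, test_ds[cfg.train.property].to_numpy()),
            ):
                m = evaluate(ys, tuned.predict(encode_matrix(sseqs)))
                metrics_rows.append(
                    {
                        "backend": kind,
                        "split": split_name,
                        "property": cfg.train.property,
                        "size": cfg.design.n,
                        "mae": m.mae,
                        "mse": m.mse,
                        "rmse": m.rmse,
                        "r2": m.r2,
                        "seed": seed_train,
                        "config_hash": manifest["config_hash"],
                    }
                )
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(metrics_rows, indent=2))
        record("metrics", metrics_path)
        manifest["timings_s"]["train"] = round(time.perf_counter() - t0, 3)

        # ---- attribute (optional)
        if cfg.attribute.enabled:
            stage = "attribute"
            t0 = time.perf_counter()
            seed_attr = cfg.seed + 4
            manifest["seeds"]["attribute"] = seed_attr
            from .attribution import (
                build_feature_matrix,
                interaction_summary,
                shap_decompose,
                train_classifiers,
                vote_select,
            )

            fm = build_feature_matrix(dataset)
            bundle = train_classifiers(
                fm, seed=seed_attr, n_search=cfg.attribute.n_search, fast=True
            )
            selected, table = vote_select(bundle.importances)
            table.to_csv(out / "importances.csv", index=False)
            record("importances", out / "importances.csv")
            rng = np.random.default_rng(seed_attr)
            rows = rng.choice(
                bundle.test_idx,
                size=min(cfg.attribute.shap_rows, bundle.test_idx.size),
                replace=False,
            )
            X_shap = fm.X.iloc[rows].to_numpy()
            inter_tables = {}
            for name, model in bundle.models.items():
                dec = shap_decompose(model, X_shap, class_index=1)
                inter_tables[name] = interaction_summary(
                    dec, list(fm.feature_names), top_k=5
                ).to_dict(orient="records")
            summary = {
                "selected_features": selected,
                "metrics": bundle.metrics.to_dict(),
                "top_interactions": inter_tables,
            }
            (out / "attribution.json").write_text(json.dumps(summary, indent=2))
            record("attribution", out / "attribution.json")
            manifest["timings_s"]["attribute"] = round(time.perf_counter() - t0, 3)

        manifest["status"] = "ok"
        save_manifest()
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = {
            "stage": stage,
            "error": repr(exc),
            "traceback": traceback.format_exc(),
        }
        save_manifest()
        if isinstance(exc, UdpepError):
            raise
        raise
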
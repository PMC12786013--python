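"""Run configuration, the end-to-end pipeline, and the ablation suite.

A single YAML document configures every stage (synthetic data, model,
training, evaluation, explanation).  :func:`run_pipeline` executes
synth -> split -> train -> eval -> explain and writes every artifact under
one run directory together with the resolved config snapshot, so a rerun
with the same config and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstats
from .fusion import IDFNet, ModelConfig, save_checkpoint
from .interpret import explain_case
from .synthdata import (
    MODALITIES,
    SyntheticSpec,
    TrimodalDataset,
    generate_dataset,
    write_dataset,
)
from .training import (
    TrainConfig,
    evaluate_missing_modality,
    train,
    train_val_test_split,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 42,
    "scale": "desk",
    "synth": {
        "n_cases": 400,
        "class_balance": 0.5,
        "image_size": 64,
        "reliability": 1.0,
        "cases_per_patient": 2,
        "n_ct_slices": 1,
        "n_histology_patches": 1,
    },
    "model": {
        "d_latent": 32,
        "d_fused": 64,
        "n_heads": 4,
        "dropout": 0.3,
        "lam": 0.01,
        "beta": 0.001,
        "fusion_mode": "attention",
        "entropy_sign": "bonus",
        "cnn_width": 8,
    },
    "train": {
        "lr": 2e-3,
        "min_lr": 1e-5,
        "batch_size": 16,
        "max_epochs": 40,
        "patience": 12,
        "weight_decay": 0.01,
    },
    "split": {"fractions": [0.70, 0.15, 0.15]},
    "eval": {"threshold": 0.5, "n_boot": 1000},
    "explain": {"n_cases": 5, "iou_threshold": 0.5},
}

PAPER_OVERRIDES = {
    "model": {"d_latent": 1024, "d_fused": 2048, "n_heads": 8},
    "train": {"lr": 1e-4, "min_lr": 1e-6, "max_epochs": 100, "patience": 10},
    "synth": {"image_size": 128},
}


def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(user: dict | None = None) -> dict:
    """Merge user settings over the scale preset over the defaults and
    validate them by constructing the stage configs."""
    user = user or {}
    cfg = DEFAULT_CONFIG
    if user.get("scale", cfg["scale"]) == "paper":
        cfg = _deep_update(cfg, PAPER_OVERRIDES)
    cfg = _deep_update(cfg, user)
    # validation: constructing the dataclasses runs every invariant check
    build_synth_spec(cfg)
    build_model_config(cfg)
    build_train_config(cfg)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def build_synth_spec(cfg: dict, seed: int | None = None) -> SyntheticSpec:
    s = cfg["synth"]
    rel = s["reliability"]
    if isinstance(rel, list):
        rel = tuple(rel) if len(rel) == 2 and all(np.isscalar(v) for v in rel) else rel
    return SyntheticSpec(
        n_cases=s["n_cases"],
        class_balance=s["class_balance"],
        image_size=s["image_size"],
        reliability=rel,
        cases_per_patient=s["cases_per_patient"],
        seed=cfg["seed"] if seed is None else seed,
        n_ct_slices=s["n_ct_slices"],
        n_histology_patches=s["n_histology_patches"],
    )


def build_model_config(cfg: dict) -> ModelConfig:
    return ModelConfig(image_size=cfg["synth"]["image_size"], seed=cfg["seed"], **cfg["model"])


def build_train_config(cfg: dict) -> TrainConfig:
    return TrainConfig(seed=cfg["seed"], scale=cfg["scale"], **cfg["train"])


# --------------------------------------------------------------------------
# evaluation report
# --------------------------------------------------------------------------


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def evaluate_model(model: IDFNet, cases: list, cfg: dict) -> dict:
    """Full evaluation report on a held-out case list."""
    labels = np.array([c.label for c in cases], dtype=int)
    record = model.predict(cases)
    scores = record.probability
    report = evalstats.metric_report(
        scores,
        labels,
        threshold=cfg["eval"]["threshold"],
        n_boot=cfg["eval"]["n_boot"],
        seed=cfg["seed"],
    )
    brier, calibration = evalstats.brier_and_calibration(scores, labels)
    dca = evalstats.decision_curve(scores, labels)
    missing = evaluate_missing_modality(model, cases, threshold=cfg["eval"]["threshold"])
    return {
        "n_cases": int(len(cases)),
        "metrics": {
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "precision": report.precision,
            "f1": report.f1,
            "auc": report.auc,
            "ci": {k: list(v) for k, v in report.ci.items()},
        },
        "brier": brier,
        "calibration": calibration.to_dict(orient="records"),
        "decision_curve": dca.to_dict(orient="records"),
        "missing_modality": missing.to_dict(orient="records"),
        "mean_routing_weights": {
            m: float(record.gate_state.routing_weights[:, i].mean())
            for i, m in enumerate(MODALITIES)
        },
        "mean_routing_entropy": float(record.gate_state.entropy.mean()),
    }


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------


def run_pipeline(cfg: dict, out_dir, write_data: bool = False) -> dict:
    """synth -> split -> train -> eval -> explain; returns the report dict.

    Every artifact lands under ``out_dir``: resolved config snapshot,
    per-epoch history CSV, best checkpoint, split assignment, report JSON
    and per-case explanation JSONs.
    """
    cfg = resolve_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    logger.info("stage synth: generating %d cases (seed %d)", cfg["synth"]["n_cases"], cfg["seed"])
    dataset = generate_dataset(build_synth_spec(cfg))
    if write_data:
        write_dataset(dataset, out / "data")

    logger.info("stage split")
    tr, va, te = train_val_test_split(dataset, tuple(cfg["split"]["fractions"]), seed=cfg["seed"])
    pd.DataFrame(
        {
            "case_id": dataset.manifest["case_id"],
            "split": ["train" if i in set(tr) else "val" if i in set(va) else "test"
                      for i in range(len(dataset))],
        }
    ).to_csv(out / "split.csv", index=False)
    train_cases = [dataset.cases[i] for i in tr]
    val_cases = [dataset.cases[i] for i in va]
    test_cases = [dataset.cases[i] for i in te]

    logger.info("stage train: %d train / %d val cases", len(train_cases), len(val_cases))
    result = train(
        train_cases,
        val_cases,
        model_config=build_model_config(cfg),
        config=build_train_config(cfg),
    )
    result.history.to_csv(out / "history.csv", index=False)
    save_checkpoint(result.model, out / "checkpoint.npz")

    logger.info("stage eval: %d test cases (best val AUC %.4f)", len(test_cases), result.best_val_auc)
    report = {
        "seed": cfg["seed"],
        "best_epoch": int(result.best_epoch),
        "best_val_auc": result.best_val_auc,
        "test": evaluate_model(result.model, test_cases, cfg),
    }

    logger.info("stage explain")
    malignant = [c for c in test_cases if c.label == 1][: cfg["explain"]["n_cases"]]
    explain_dir = out / "explanations"
    explain_dir.mkdir(exist_ok=True)
    ious, attributions = [], []
    for case in malignant:
        bundle = explain_case(result.model, case, cfg["explain"]["iou_threshold"])
        ious.extend(bundle.iou.values())
        attributions.append(bundle.attribution.phi)
        with open(explain_dir / f"{case.case_id}.json", "w") as fh:
            json.dump(
                _round_floats(
                    {
                        "case_id": case.case_id,
                        "probability": bundle.probability,
                        "iou": bundle.iou,
                        "shapley": bundle.attribution.phi,
                        "baseline": bundle.attribution.baseline,
                        "full": bundle.attribution.full,
                    }
                ),
                fh,
                indent=2,
                sort_keys=True,
            )
    report["explain"] = {
        "n_explained": len(malignant),
        "mean_saliency_iou": float(np.mean(ious)) if ious else None,
        "mean_abs_shapley": {
            m: float(np.mean([abs(a[m]) for a in attributions])) if attributions else None
            for m in MODALITIES
        },
    }

    with open(out / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
    return report


# --------------------------------------------------------------------------
# ablation suite
# --------------------------------------------------------------------------

ABLATION_CONFIGURATIONS = (
    # (name, fusion_mode, lam) — lam 0 disables entropy-regularized routing
    ("baseline_no_fusion", "concat", 0.0),
    ("drm_only", "weighted_sum", None),
    ("drm_caf", "attention", None),
    ("full", "attention", None),
)

ABLATION_REPORT_SCHEMA = {
    "type": "object",
    "required": ["seed", "rows"],
    "rows_item_required": ["configuration", "accuracy", "auc", "best_val_auc"],
}


def validate_ablation_report(report: dict) -> None:
    """Check an ablation report against :data:`ABLATION_REPORT_SCHEMA`."""
    for key in ABLATION_REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"ablation report missing key {key!r}")
    if not isinstance(report["rows"], list) or not report["rows"]:
        raise ValueError("ablation report rows must be a non-empty list")
    for row in report["rows"]:
        for key in ABLATION_REPORT_SCHEMA["rows_item_required"]:
            if key not in row:
                raise ValueError(f"ablation row missing key {key!r}")
        for key in ("accuracy", "auc", "best_val_auc"):
            if not 0.0 <= float(row[key]) <= 1.0:
                raise ValueError(f"ablation row field {key} outside [0, 1]")


def ablation_suite(cfg: dict, out_dir=None) -> dict:
    """Train the four fusion configurations on one identical split/seed and
    report accuracy + AUC per configuration."""
    cfg = resolve_config(cfg)
    dataset = generate_dataset(build_synth_spec(cfg))
    tr, va, te = train_val_test_split(dataset, tuple(cfg["split"]["fractions"]), seed=cfg["seed"])
    train_cases = [dataset.cases[i] for i in tr]
    val_cases = [dataset.cases[i] for i in va]
    test_cases = [dataset.cases[i] for i in te]
    labels = np.array([c.label for c in test_cases], dtype=int)

    rows = []
    for name, mode, lam in ABLATION_CONFIGURATIONS:
        mc = build_model_config(cfg)
        mc.fusion_mode = mode
        if lam is not None:
            mc.lam = lam
        logger.info("ablation %s (fusion=%s lam=%s)", name, mode, mc.lam)
        result = train(train_cases, val_cases, model_config=mc, config=build_train_config(cfg))
        record = result.model.predict(test_cases)
        pred = (record.probability >= cfg["eval"]["threshold"]).astype(int)
        rows.append(
            {
                "configuration": name,
                "fusion_mode": mode,
                "lam": mc.lam,
                "accuracy": float((pred == labels).mean()),
                "auc": evalstats.auc_mann_whitney(record.probability, labels),
                "best_val_auc": result.best_val_auc,
            }
        )
    report = {"seed": cfg["seed"], "rows": _round_floats(rows)}
    validate_ablation_report(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "ablation.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
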
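"""End-to-end orchestration: phantoms -> segmentation -> reconstruction ->
GH crops -> classification -> metrics -> rater-agreement analysis.

Every stage writes its artifacts plus a manifest (stage inputs, a hash of
the stage-relevant config, the stage seed) into the run directory;
re-running with the same config reproduces all CSV/JSON reports bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, arthronet, celunet, metrics, phantoms, reconstruct
from .volumes import save_nifti

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # phantoms
    n_cases: int = 30
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 25.0
    label_noise_p: float = 0.0
    n_test: int = 5
    n_val: int = 5
    # segmentation
    seg_base_channels: int = 4
    seg_depth: int = 3
    seg_epochs: int = 10
    seg_patience: int = 4
    seg_lr: float = 3e-3
    # classifier
    crop_size_mm: float = 64.0
    cls_channels: tuple[int, ...] = (8, 16, 32)
    cls_epochs: int = 25
    cls_patience: int = 6
    cls_lr: float = 3e-3
    # rater panel
    n_raters: int = 10
    rater_sensitivity: float = 0.75
    rater_bias_reverse: float = 0.05

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("grid_shape", "spacing", "cls_channels"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _manifest(out: Path, stage: str, cfg: RunConfig, inputs: list[str],
              outputs: list[str]) -> None:
    man = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.stage_seed(stage),
        "inputs": inputs,
        "outputs": outputs,
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(man, indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        cases = phantoms.generate_cohort(
            cfg.n_cases, seed=cfg.stage_seed(stage),
            grid_shape=cfg.grid_shape, spacing=cfg.spacing,
            noise_sd=cfg.noise_sd, label_noise_p=cfg.label_noise_p,
        )
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for i, c in enumerate(cases):
            save_nifti(c.image, vol_dir / f"case_{i:04d}_image.nii.gz")
            save_nifti(c.labels, vol_dir / f"case_{i:04d}_labels.nii.gz")
        labels_df = pd.DataFrame([
            {"case_id": f"case_{i:04d}", "os": c.os_grade, "js": c.js_grade,
             "hsa": c.hsa_grade, "implant": c.implant}
            for i, c in enumerate(cases)
        ])
        labels_df.to_csv(out / "labels.csv", index=False)
        _manifest(out, stage, cfg, [], ["volumes/", "labels.csv"])

        n_test, n_val = cfg.n_test, cfg.n_val
        if len(cases) < n_test + n_val + 2:
            raise ValueError("not enough cases for the requested split")
        test, val, train = (cases[:n_test], cases[n_test:n_test + n_val],
                            cases[n_test + n_val:])

        stage = "train_seg"
        arch = celunet.ArchConfig(depth=cfg.seg_depth, base_channels=cfg.seg_base_channels)
        seg = celunet.train_segmentation(
            train, val, arch=arch, max_epochs=cfg.seg_epochs,
            patience=cfg.seg_patience, lr=cfg.seg_lr, seed=cfg.stage_seed(stage),
        )
        seg.history.to_csv(out / "seg_history.csv", index=False)
        celunet.save_checkpoint(seg.model, out / "seg_model.npz")
        _manifest(out, stage, cfg, ["volumes/"],
                  ["seg_history.csv", "seg_model.npz"])

        stage = "segment"
        pred_labels = []
        for i, c in enumerate(test):
            pl = celunet.predict_labels(seg.model, c.image)
            pred_labels.append(pl)
            save_nifti(pl, vol_dir / f"case_{i:04d}_pred.nii.gz")
        _manifest(out, stage, cfg, ["seg model"], ["volumes/*_pred.nii.gz"])

        stage = "reconstruct"
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for i, pl in enumerate(pred_labels):
            for cid, name in ((1, "humerus"), (2, "scapula")):
                if (pl.data == cid).any():
                    mesh = reconstruct.reconstruct_mesh(pl, class_id=cid)
                    reconstruct.save_stl(mesh, mesh_dir / f"case_{i:04d}_{name}.stl")
        _manifest(out, stage, cfg, ["volumes/*_pred.nii.gz"], ["meshes/"])

        stage = "gh_crop"

        def crops_for(case_list):
            pairs = []
            for c in case_list:
                region = reconstruct.extract_gh_region(
                    c.labels, image=c.image, crop_size_mm=cfg.crop_size_mm)
                pairs.append((region.image_crop.data,
                              arthronet.CaseLabels(c.os_grade, c.js_grade,
                                                   c.hsa_grade, c.implant)))
            return pairs

        train_crops, val_crops, test_crops = map(crops_for, (train, val, test))
        _manifest(out, stage, cfg, ["volumes/"], ["(in-memory GH crops)"])

        stage = "train_cls"
        cls = arthronet.train_classifier(
            train_crops, val_crops, encoder_channels=cfg.cls_channels,
            max_epochs=cfg.cls_epochs, patience=cfg.cls_patience,
            lr=cfg.cls_lr, seed=cfg.stage_seed(stage),
        )
        cls.history.to_csv(out / "cls_history.csv", index=False)
        arthronet.save_checkpoint(cls.model, out / "cls_model.npz")
        _manifest(out, stage, cfg, ["GH crops"],
                  ["cls_history.csv", "cls_model.npz"])

        stage = "classify"
        preds = arthronet.predict_tasks(cls.model, [c for c, _ in test_crops])
        pred_df = pd.DataFrame(preds, columns=["os", "js", "hsa", "implant"])
        pred_df.insert(0, "case_id", [f"case_{i:04d}" for i in range(len(test))])
        pred_df.to_csv(out / "cls_predictions.csv", index=False)
        _manifest(out, stage, cfg, ["cls model"], ["cls_predictions.csv"])

        stage = "evaluate"
        seg_reports = [metrics.segmentation_metrics(pl, c.labels)
                       for pl, c in zip(pred_labels, test)]
        report = {
            "segmentation": {
                "mean_foreground_dice": float(np.mean(
                    [r.extra["mean_foreground_dice"] for r in seg_reports])),
                "mean_foreground_jaccard": float(np.mean(
                    [r.extra["mean_foreground_jaccard"] for r in seg_reports])),
            },
            "classification": {},
        }
        truth = np.array([lab.as_tuple() for _, lab in test_crops])
        for t, name in enumerate(arthronet.TASK_NAMES):
            n_cls = 3 if name in ("OS", "JS") else 2
            rep = metrics.classification_report(preds[:, t], truth[:, t], n_cls)
            report["classification"][name] = {
                "accuracy": rep.accuracy, "macro_f1": rep.macro_f1,
                "weighted_f1": rep.weighted_f1,
            }
        (out / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _manifest(out, stage, cfg, ["cls_predictions.csv"], ["metrics.json"])

        stage = "agreement"
        profiles = [phantoms.RaterProfile(cfg.rater_sensitivity, cfg.rater_sensitivity,
                                          cfg.rater_bias_reverse)
                    for _ in range(cfg.n_raters)]
        panel = phantoms.generate_rater_panel(test, profiles,
                                              seed=cfg.stage_seed(stage))
        panel.to_csv(out / "rater_panel.csv", index=False)
        try:
            stats = agreement.fleiss_kappa(
                agreement.ratings_to_matrix(panel, categories=2))
        except agreement.UndefinedKappaError:
            stats = None  # degenerate unanimous panel on a tiny test split
        entropies = agreement.panel_entropies(panel)
        entropies.to_csv(out / "case_entropy.csv", index=False)
        truths = np.array([c.implant for c in test])
        model_correct = preds[:, 3] == truths
        votes = panel[[c for c in panel.columns if c != "case_id"]].to_numpy()
        majority = (votes.mean(axis=1) >= 0.5).astype(int)
        majority_correct = majority == truths
        _, p_mcnemar = agreement.mcnemar_test(model_correct, majority_correct)
        try:
            folds = min(5, len(truths) // 2)
            consensus_acc = agreement.virtual_consensus(
                votes, truths, folds=folds, seed=cfg.stage_seed(stage))
        except ValueError:
            consensus_acc = None  # too few cases or a single class in the test split
        agree_report = {
            "virtual_consensus_accuracy": consensus_acc,
            "fleiss_kappa": stats.kappa if stats else None,
            "observed_agreement": stats.observed_agreement if stats else None,
            "expected_agreement": stats.expected_agreement if stats else None,
            "mean_entropy_bits": float(entropies["entropy_bits"].mean()),
            "model_vs_majority_mcnemar_p": p_mcnemar,
            "model_it_accuracy": float(model_correct.mean()),
            "majority_vote_accuracy": float(majority_correct.mean()),
        }
        (out / "agreement.json").write_text(
            json.dumps(agree_report, indent=2, sort_keys=True))
        _manifest(out, stage, cfg, ["rater_panel.csv"],
                  ["agreement.json", "case_entropy.csv"])
    except Exception as exc:  # noqa: BLE001 - halt with the stage name
        raise StageError(stage, exc) from exc
    return out
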
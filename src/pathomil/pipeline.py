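"""End-to-end orchestration: simulate -> label-reports -> preprocess ->
train -> evaluate as one reproducible, seeded run.

Each stage writes its artifacts under the run directory and never mutates
another stage's outputs; the run log records config hash, seed and output
checksums per stage.  Later stages consume the declared outputs of earlier
ones (in memory within one run, from files where re-loading is supported).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .labeler import (
    LabelerConfig,
    label_corpus,
    label_report,
    load_gazetteer,
    read_reports_jsonl,
    write_reports_jsonl,
    write_trace_jsonl,
)
from .backbones import BackboneSpec, make_backbone
from .metrics import cohen_kappa, evaluate_predictions, find_mislabeled
from .mil import Bag, TrainConfig, cross_validate, predict_wsi, save_checkpoint
from .preprocess import PreprocessConfig, compute_tissue_mask, extract_patches, patch_manifest
from .schema import frame_to_labels, labels_to_frame, read_label_csv, write_label_csv
from .synthetic import CorpusConfig, corpus_label_frames, synth_corpus
from .visualize import render_heatmap

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "label_reports", "preprocess", "train", "evaluate")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    labeler: LabelerConfig = field(default_factory=LabelerConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    backbone: str = "tiny"
    k_folds: int = 2
    label_source: str = "auto"  # auto (report labeler) | noisy | gt
    version: str = __version__

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["labeler"]["unspecified_grade_class"] = self.labeler.unspecified_grade_class.name
        payload["labeler"]["fallback_class"] = self.labeler.fallback_class.name
        payload["corpus"]["class_prevalence"] = {
            "|".join(sorted(k)): v for k, v in self.corpus.class_prevalence.items()
        }
        payload["stages"] = list(self.stages)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text)
        payload.pop("version", None)
        corpus = payload.pop("corpus", {})
        if "class_prevalence" in corpus:
            corpus["class_prevalence"] = {
                frozenset(k.split("|")): v for k, v in corpus["class_prevalence"].items()
            }
        labeler = payload.pop("labeler", {})
        labeler.pop("fallback_class", None)
        train = payload.pop("train", {})
        train.pop("grid", None)
        return cls(
            corpus=CorpusConfig(**corpus),
            labeler=LabelerConfig(**labeler),
            preprocess=PreprocessConfig(**payload.pop("preprocess", {})),
            train=TrainConfig(**train),
            stages=tuple(payload.pop("stages", ALL_STAGES)),
            **payload,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    for stage in config.stages:
        if stage not in ALL_STAGES:
            problems.append(f"stages: unknown stage {stage!r}")
    n_patients = max(1, -(-config.corpus.n_cases // config.corpus.bags_per_patient))
    if "train" in config.stages and config.k_folds > n_patients:
        problems.append(
            f"k_folds: k={config.k_folds} exceeds the {n_patients} patients implied by "
            "corpus.n_cases / corpus.bags_per_patient"
        )
    if not 0 < config.train.decision_threshold < 1:
        problems.append(
            f"train.decision_threshold: {config.train.decision_threshold} outside (0, 1)"
        )
    if config.preprocess.patch_size > config.corpus.slide_size:
        problems.append("preprocess.patch_size: larger than corpus.slide_size")
    if config.label_source not in {"auto", "noisy", "gt"}:
        problems.append(f"label_source: unknown source {config.label_source!r}")
    if "train" in config.stages and "preprocess" not in config.stages:
        problems.append("train: requires the preprocess stage in the same run")
    return problems


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()[:12]


def _write_png(path: Path, array: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, array)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the summary report.

    The summary is also written to ``summary.json`` in the run directory,
    along with a stage log of config hash, seed and artifact checksums.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())
    config_hash = hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]

    summary: dict = {"config_hash": config_hash, "seed": config.seed, "stages": {}}
    log: list[dict] = []
    state: dict = {}

    def record(stage: str, outputs: list[Path]) -> None:
        log.append(
            {
                "stage": stage,
                "config_hash": config_hash,
                "seed": config.seed,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "time": time.time(),
            }
        )

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        outputs = _STAGE_FUNCS[stage](config, run_dir, state, summary)
        record(stage, outputs)

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (run_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return summary


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config: RunConfig, run_dir: Path, state: dict, summary: dict) -> list[Path]:
    corpus_cfg = dataclasses.replace(config.corpus, seed=config.seed)
    cases, manifest = synth_corpus(corpus_cfg)
    state["cases"] = cases
    gt_frame, noisy_frame = corpus_label_frames(cases)
    slides_dir = run_dir / "slides"
    masks_dir = run_dir / "masks"
    slides_dir.mkdir(exist_ok=True)
    masks_dir.mkdir(exist_ok=True)
    for case in cases:
        _write_png(slides_dir / f"{case.case_id}.png", case.slide.pixels)
        _write_png(masks_dir / f"{case.case_id}.png", (case.region_mask + 1).astype(np.uint8))
    write_reports_jsonl([c.report for c in cases], run_dir / "reports.jsonl")
    write_label_csv(gt_frame, run_dir / "labels_gt.csv")
    write_label_csv(noisy_frame, run_dir / "labels_noisy.csv")
    manifest.to_csv(run_dir / "manifest.csv", index=False)
    summary["stages"]["simulate"] = {
        "n_cases": len(cases),
        "n_corrupted": int(manifest["corrupted"].sum()),
    }
    return [run_dir / n for n in ("reports.jsonl", "labels_gt.csv", "labels_noisy.csv", "manifest.csv")]


def _stage_label_reports(config: RunConfig, run_dir: Path, state: dict, summary: dict) -> list[Path]:
    if "cases" in state:
        reports = [c.report for c in state["cases"]]
    elif (run_dir / "reports.jsonl").exists():
        reports = read_reports_jsonl(run_dir / "reports.jsonl")
    else:
        raise PipelineError("label_reports: no reports found; enable the simulate stage")
    gazetteer = load_gazetteer()
    gt = None
    if (run_dir / "labels_gt.csv").exists():
        gt_frame = read_label_csv(run_dir / "labels_gt.csv")
        # report ids are case ids + '-rep'; align on the case id
        gt = gt_frame.assign(case_id=gt_frame["case_id"].astype(str) + "-rep")
    table, agreement = label_corpus(reports, gazetteer, config.labeler, gt=gt)
    table = table.assign(case_id=table["case_id"].str.replace("-rep$", "", regex=True))
    write_label_csv(table, run_dir / "labels_auto.csv")
    traces = {
        r.report_id: label_report(r, gazetteer, config.labeler)[1] for r in reports
    }
    write_trace_jsonl(traces, run_dir / "concept_trace.jsonl")
    summary["stages"]["label_reports"] = {"n_reports": len(reports), **agreement}
    return [run_dir / "labels_auto.csv", run_dir / "concept_trace.jsonl"]


def _training_labels(config: RunConfig, run_dir: Path, case_ids: list[str]) -> np.ndarray:
    source = {
        "auto": "labels_auto.csv",
        "noisy": "labels_noisy.csv",
        "gt": "labels_gt.csv",
    }[config.label_source]
    path = run_dir / source
    if not path.exists():
        raise PipelineError(
            f"train: label table {source} missing; enable the "
            f"{'label_reports' if config.label_source == 'auto' else 'simulate'} stage"
        )
    ids, labels = frame_to_labels(read_label_csv(path))
    order = {cid: i for i, cid in enumerate(ids)}
    return labels[[order[c] for c in case_ids]]


def _stage_preprocess(config: RunConfig, run_dir: Path, state: dict, summary: dict) -> list[Path]:
    if "cases" not in state:
        raise PipelineError("preprocess: no slides in this run; enable the simulate stage")
    cases = state["cases"]
    records_all = []
    bags: list[Bag] = []
    patch_gts: list[np.ndarray] = []
    for case in cases:
        mask = compute_tissue_mask(case.slide)
        records, tiles = extract_patches(case.slide, mask, config.preprocess)
        if not records:
            continue
        ps = config.preprocess.patch_size
        gt = np.array([case.patch_gt[r.y // ps, r.x // ps] for r in records], dtype=np.int8)
        bags.append(
            Bag(
                slide_id=case.case_id,
                patient_id=case.patient_id,
                tiles=tiles,
                coords=[(r.x, r.y) for r in records],
                label=None if case.gt_label is None else case.gt_label,
                patch_gt=gt,
            )
        )
        patch_gts.append(gt)
        records_all.extend(records)
    state["bags"] = bags
    manifest = patch_manifest(records_all)
    manifest.to_csv(run_dir / "patches.csv", index=False)
    summary["stages"]["preprocess"] = {
        "n_slides": len(bags),
        "n_patches": len(records_all),
    }
    return [run_dir / "patches.csv"]


def _stage_train(config: RunConfig, run_dir: Path, state: dict, summary: dict) -> list[Path]:
    bags = state.get("bags")
    if not bags:
        raise PipelineError("train: no bags available; enable the preprocess stage")
    labels = _training_labels(config, run_dir, [b.slide_id for b in bags])
    from .mil import replace_label

    train_bags = [replace_label(b, labels[i]) for i, b in enumerate(bags)]
    state["bags"] = train_bags
    backbone = make_backbone(BackboneSpec(architecture=config.backbone, seed=config.seed))
    state["backbone"] = backbone
    train_cfg = dataclasses.replace(config.train, seed=config.seed)
    result = cross_validate(train_bags, backbone, train_cfg, k=config.k_folds, seed=config.seed)
    state["cv"] = result
    ckpt_dir = run_dir / "checkpoints"
    ckpt_dir.mkdir(exist_ok=True)
    outputs = []
    for fold, head in enumerate(result["heads"]):
        path = ckpt_dir / f"fold{fold}.npz"
        save_checkpoint(path, head, train_cfg, BackboneSpec(architecture=config.backbone, seed=config.seed))
        outputs.append(path)
    summary["stages"]["train"] = {
        "k": config.k_folds,
        "micro_accuracy": result["micro_accuracy"],
        "weighted_f1": result["weighted_f1"],
        "folds": [
            {k: v for k, v in m.items() if k != "fold"} | {"fold": m["fold"]}
            for m in result["folds"]
        ],
    }
    return outputs


def _stage_evaluate(config: RunConfig, run_dir: Path, state: dict, summary: dict) -> list[Path]:
    result = state.get("cv")
    bags = state.get("bags")
    if result is None or bags is None:
        raise PipelineError("evaluate: no trained models in this run; enable the train stage")
    backbone = state["backbone"]
    plan = result["plan"]
    gt_frame = read_label_csv(run_dir / "labels_gt.csv") if (run_dir / "labels_gt.csv").exists() else None

    rows, gts, preds, probs = [], [], [], []
    patch_gt_all, patch_pred_all = [], []
    gt_by_case = {}
    if gt_frame is not None:
        ids, gt_labels = frame_to_labels(gt_frame)
        gt_by_case = dict(zip(ids, gt_labels))
    for bag in bags:
        fold = plan.fold_of(bag.patient_id)
        head = result["heads"][fold]
        label, prob, att = predict_wsi(bag, backbone, head, config.train.decision_threshold)
        gt_label = gt_by_case.get(bag.slide_id, bag.label)
        rows.append({"case_id": bag.slide_id, **{f"p_{i}": p for i, p in enumerate(prob)}})
        gts.append(gt_label)
        preds.append(label)
        probs.append(prob)
        if bag.patch_gt is not None:
            from .mil import embed_bag, patch_predict

            emb = embed_bag(bag, backbone, head)
            _, hard = patch_predict(emb, head)
            keep = bag.patch_gt >= 0
            patch_gt_all.append(bag.patch_gt[keep])
            patch_pred_all.append(hard[keep])
    gt_arr, pred_arr, prob_arr = np.vstack(gts), np.vstack(preds), np.vstack(probs)
    report = evaluate_predictions(gt_arr, pred_arr, prob_arr)
    metrics = report.to_dict()
    if patch_gt_all:
        metrics["patch_kappa"] = cohen_kappa(
            np.concatenate(patch_gt_all), np.concatenate(patch_pred_all)
        )
    pred_frame = labels_to_frame([r["case_id"] for r in rows], pred_arr)
    for i in range(5):
        pred_frame[f"prob_{i}"] = prob_arr[:, i]
    pred_frame.to_csv(run_dir / "predictions.csv", index=False)
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    # mislabel protocol when both label tables exist
    if (run_dir / "labels_auto.csv").exists() and gt_frame is not None:
        auto_frame = read_label_csv(run_dir / "labels_auto.csv")
        mislabeled = find_mislabeled(auto_frame, gt_frame)
        metrics["n_mislabeled"] = len(mislabeled)
        (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    # one attention heatmap for illustration
    cases = state.get("cases")
    if cases:
        bag = bags[0]
        case = next(c for c in cases if c.case_id == bag.slide_id)
        fold = plan.fold_of(bag.patient_id)
        _, _, att = predict_wsi(bag, backbone, result["heads"][fold])
        from .preprocess import PatchRecord

        records = [
            PatchRecord(bag.slide_id, x, y, config.preprocess.target_magnification, 1.0)
            for x, y in bag.coords
        ]
        overlay = render_heatmap(case.slide.pixels, records, att, int(np.argmax(att.sum(axis=1))))
        _write_png(run_dir / "heatmap_example.png", (overlay * 255).astype(np.uint8))
    summary["stages"]["evaluate"] = metrics
    return [run_dir / "predictions.csv", run_dir / "metrics.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "label_reports": _stage_label_reports,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}
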
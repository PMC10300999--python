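"""End-to-end orchestration: simulate -> preprocess -> features -> labels ->
train -> evaluate -> compare, driven by one YAML-able config.

Each stage reads and writes plain files under the run directory, so stages
are idempotent given identical inputs and seeds; a manifest records the
config hash, artifact paths and per-stage wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import difficulty, model, preprocess, roc, synthetic
from .errors import InputError, ReadiffError
from .radiomics import FEATURE_NAMES, extract_all

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "features", "labels", "train", "evaluate", "compare")
ROI_KINDS = ("square", "retroareolar", "whole")


@dataclass
class RunConfig:
    outdir: str = "runs/demo"
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    stages: tuple[str, ...] = STAGES
    bases: tuple[str, ...] = ("FP", "FN", "location")
    roi_kinds: tuple[str, ...] = ROI_KINDS
    normalized_tracks: tuple[bool, ...] = (True, False)
    Ng: int = 32
    opening_radius: int = 5
    grid: model.HyperGrid = field(default_factory=model.HyperGrid.reduced)
    cv_seed: int = 0
    n_boot: int = 2000
    threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = synthetic.SyntheticConfig(**kwargs["synthetic"])
        if "grid" in kwargs:
            kwargs["grid"] = model.HyperGrid(**{k: tuple(v) for k, v in kwargs["grid"].items()})
        for key in ("stages", "bases", "roi_kinds", "normalized_tracks"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**kwargs)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise InputError(f"unknown stages: {sorted(bad)}")
        return cfg

    def hash(self) -> str:
        blob = json.dumps({
            "synthetic": dataclasses.asdict(self.synthetic),
            "bases": self.bases, "roi_kinds": self.roi_kinds,
            "normalized_tracks": self.normalized_tracks, "Ng": self.Ng,
            "opening_radius": self.opening_radius,
            "grid": dataclasses.asdict(self.grid), "cv_seed": self.cv_seed,
            "n_boot": self.n_boot, "threshold": self.threshold,
        }, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_view(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    cases, truths = synthetic.generate_cohort(cfg.synthetic)
    responses = synthetic.simulate_reader_panel(cases, truths, cfg.synthetic)
    synthetic.write_cohort(outdir, cases, truths, responses, cfg.synthetic)


def stage_preprocess_features(cfg: RunConfig, outdir: Path) -> None:
    """Segment, delineate ROIs and extract features in one pass.

    Writes ``features.csv`` (one row per case/view/roi/track with 203 named
    columns) and ``roi_boxes.json`` recording bounding boxes and any
    pectoral line endpoints.
    """
    truth = pd.read_csv(outdir / "truth.csv")
    case_ids = sorted(truth["case_id"].unique())
    rows, boxes = [], {}
    for cid in case_ids:
        for view in synthetic.VIEWS:
            img = _read_view(outdir / "images" / f"{cid}_{view}.png")
            img = preprocess.mirror_to_chest_left(img, view)
            bm = preprocess.segment_breast(img, opening_radius=cfg.opening_radius)
            if "MLO" in view:
                bm = preprocess.remove_pectoral(img, bm, view)
            rois = preprocess.extract_rois(img, bm, view_tag=view)
            boxes[f"{cid}_{view}"] = {
                "pectoral_line": bm.pectoral_line,
                **{k: list(r.bbox) for k, r in rois.items()},
            }
            for kind in cfg.roi_kinds:
                roi = rois[kind]
                for norm in cfg.normalized_tracks:
                    r = preprocess.zscore_roi(roi) if norm else roi
                    fv = extract_all(r, Ng=cfg.Ng)
                    rows.append({"case_id": cid, "view": view, "roi_kind": kind,
                                 "normalized": norm,
                                 **dict(zip(fv.names, fv.values))})
    pd.DataFrame(rows).to_csv(outdir / "features.csv", index=False)

    def _jsonable(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return list(o)

    (outdir / "roi_boxes.json").write_text(json.dumps(boxes, indent=2, default=_jsonable))


def stage_labels(cfg: RunConfig, outdir: Path) -> None:
    truth = pd.read_csv(outdir / "truth.csv")
    responses = pd.read_csv(outdir / "responses.csv")
    frames = []
    for basis in cfg.bases:
        summaries = difficulty.summarize_errors(
            responses, truth, basis, radius=cfg.synthetic.loc_radius)
        labels = difficulty.tertile_split(summaries)
        df = difficulty.labels_frame(labels)
        df["proportion"] = [s.proportion for s in sorted(summaries, key=lambda s: (s.proportion, s.case_id))]
        frames.append(df)
    pd.concat(frames).to_csv(outdir / "labels.csv", index=False)


def _channels_for(basis: str, features: pd.DataFrame, truth: pd.DataFrame,
                  roi_kind: str, normalized: bool, case_ids) -> dict[str, pd.DataFrame]:
    sub = features[(features["roi_kind"] == roi_kind) & (features["normalized"] == normalized)]
    sides = truth.groupby("case_id")["lesion_side"].first()
    channels: dict[str, dict] = {}
    for cid in case_ids:
        if basis == "FP":
            view_map = {v: v for v in model.ALL_VIEWS}
        else:
            side = sides.get(cid)
            view_map = {f"{side}CC": "CC", f"{side}MLO": "MLO"}
        for view, channel in view_map.items():
            row = sub[(sub["case_id"] == cid) & (sub["view"] == view)]
            if len(row) != 1:
                raise InputError(f"missing features for {cid}/{view}")
            channels.setdefault(channel, {})[cid] = row.iloc[0][FEATURE_NAMES].to_numpy(dtype=float)
    return {ch: pd.DataFrame.from_dict(d, orient="index", columns=FEATURE_NAMES)
            for ch, d in channels.items()}


def stage_train(cfg: RunConfig, outdir: Path) -> None:
    features = pd.read_csv(outdir / "features.csv")
    labels_all = pd.read_csv(outdir / "labels.csv")
    truth = pd.read_csv(outdir / "truth.csv")
    preds_rows = []
    log_path = outdir / "chosen_hyperparams.jsonl"
    with open(log_path, "w") as logf:
        for basis in cfg.bases:
            lb = labels_all[labels_all["basis"] == basis]
            y = difficulty.modelling_labels([
                difficulty.DifficultyLabel(r.case_id, r.basis, r.tertile)
                for r in lb.itertuples()])
            for roi_kind in cfg.roi_kinds:
                for norm in cfg.normalized_tracks:
                    channels = _channels_for(basis, features, truth, roi_kind, norm, list(y.index))
                    plan = model.FoldPlan(seed=cfg.cv_seed)
                    preds, log = model.nested_cv(channels, y, grid=cfg.grid, plan=plan)
                    for entry in log:
                        logf.write(json.dumps({"basis": basis, "roi_kind": roi_kind,
                                               "normalized": norm, **entry}) + "\n")
                    for p in preds:
                        preds_rows.append({
                            "basis": basis, "roi_kind": roi_kind, "normalized": norm,
                            "case_id": p.case_id, "fused": p.fused, "label": p.label,
                            **{f"p_{ch}": v for ch, v in p.view_probs.items()}})
    pd.DataFrame(preds_rows).to_csv(outdir / "preds.csv", index=False)


def stage_evaluate(cfg: RunConfig, outdir: Path) -> None:
    preds = pd.read_csv(outdir / "preds.csv")
    metrics = {}
    for (basis, roi_kind, norm), grp in preds.groupby(["basis", "roi_kind", "normalized"]):
        res = roc.roc_result(grp["fused"], grp["label"], threshold=cfg.threshold,
                             n_boot=cfg.n_boot, seed=cfg.cv_seed)
        metrics[f"{basis}|{roi_kind}|{'normalized' if norm else 'raw'}"] = dataclasses.asdict(res)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))


def stage_compare(cfg: RunConfig, outdir: Path) -> None:
    """DeLong tests: normalization effect per ROI, and ROI-placement pairs."""
    preds = pd.read_csv(outdir / "preds.csv")
    out = []
    for basis in cfg.bases:
        sub = preds[preds["basis"] == basis]
        if len(cfg.normalized_tracks) == 2:
            for roi_kind in cfg.roi_kinds:
                a = sub[(sub["roi_kind"] == roi_kind) & sub["normalized"]].set_index("case_id")
                b = sub[(sub["roi_kind"] == roi_kind) & ~sub["normalized"]].set_index("case_id")
                ids = sorted(set(a.index) & set(b.index))
                cmp = roc.delong_test(a.loc[ids, "fused"], b.loc[ids, "fused"], a.loc[ids, "label"])
                out.append({"basis": basis, "contrast": f"normalized vs raw ({roi_kind})",
                            **dataclasses.asdict(cmp)})
        for norm in cfg.normalized_tracks:
            for r1, r2 in [("square", "retroareolar"), ("retroareolar", "whole"), ("square", "whole")]:
                if r1 not in cfg.roi_kinds or r2 not in cfg.roi_kinds:
                    continue
                a = sub[(sub["roi_kind"] == r1) & (sub["normalized"] == norm)].set_index("case_id")
                b = sub[(sub["roi_kind"] == r2) & (sub["normalized"] == norm)].set_index("case_id")
                ids = sorted(set(a.index) & set(b.index))
                cmp = roc.delong_test(a.loc[ids, "fused"], b.loc[ids, "fused"], a.loc[ids, "label"])
                out.append({"basis": basis, "normalized": norm,
                            "contrast": f"{r1} vs {r2}", **dataclasses.asdict(cmp)})
    (outdir / "comparisons.json").write_text(json.dumps(out, indent=2))


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess_features,   # preprocess + features share one pass
    "features": lambda cfg, outdir: None,      # produced by the preprocess pass
    "labels": stage_labels,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "compare": stage_compare,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.hash(), "stages": {}, "artifacts": {}}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](cfg, outdir)
        except ReadiffError as exc:
            manifest["failed_stage"] = stage
            (outdir / "manifest.run.json").write_text(json.dumps(manifest, indent=2))
            raise ReadiffError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
    for name in ("features.csv", "labels.csv", "preds.csv", "metrics.json", "comparisons.json"):
        if (outdir / name).exists():
            manifest["artifacts"][name] = str(outdir / name)
    (outdir / "manifest.run.json").write_text(json.dumps(manifest, indent=2))
    return manifest
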
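"""End-to-end experiment orchestration with machine-readable reports.

Two experiments mirror the study's analysis structure at desk scale:

* :func:`run_comparison_experiment` — synthesise a healthy/cancerous
  section, render it through both the nanocavity (NOS) and the
  weak-contrast glass forward model, sample five regions per class,
  compute the 5×5 pairwise KDE-IoU (plus Frobenius and Chamfer) matrices
  per rendering mode, and t-test the two sets of 25 IoU values.
* :func:`run_screening_experiment` — synthesise labelled tiles with a
  subject-level train/test split, score them with the shallow colour
  baseline, and report the full confusion-matrix / ROC metric suite.

Every report echoes its configuration and seed so a re-run reproduces all
numbers bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, metrics, synthetic
from .errors import InputError

__all__ = ["RunConfig", "RunReport", "run_comparison_experiment",
           "run_screening_experiment"]

log = logging.getLogger("noscolor")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run.

    Desk-scale defaults: 5 regions of 27×27 px per class on a 160×160 px
    section, 32³ KDE grid, 32×32 colour lookup table.  The 81×81 px region
    of the full protocol is configurable via ``region_px``.
    """

    seed: int = 0
    section_height: int = 160
    section_width: int = 160
    n_regions: int = 5
    region_px: int = 27
    kde_grid_size: int = 32
    lut_size: int = 32
    noise_sd: float = 0.01
    ri_model: dict = field(default_factory=lambda: {
        "healthy": (1.27, 0.02), "cancerous": (1.37, 0.02)})
    thickness_model_um: dict = field(default_factory=lambda: {
        "healthy": (0.3, 1.0), "cancerous": (0.3, 1.0)})
    cavity_thickness_nm: float = 111.0
    illuminant: str = "D65"
    # screening settings
    n_train_per_class: int = 40
    n_test_per_class: int = 40
    tile_px: int = 24
    classifier: str = "centroid"
    decision_threshold: float = 0.0
    out_dir: str | None = None
    dry_run: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ri_model", "thickness_model_um"):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)

    def section_spec(self) -> synthetic.SectionSpec:
        return synthetic.SectionSpec(
            height=self.section_height, width=self.section_width,
            layout="split", ri_model=dict(self.ri_model),
            thickness_model_um=dict(self.thickness_model_um),
            cavity_thickness_nm=self.cavity_thickness_nm,
            illuminant=self.illuminant, noise_sd=self.noise_sd,
            seed=self.seed)


@dataclass(frozen=True)
class RunReport:
    """Stage outputs plus provenance (config echo, seeds, wall-clock)."""

    experiment: str
    config: RunConfig
    results: dict
    timings_s: dict
    schema_version: int = SCHEMA_VERSION

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"cannot serialise {type(o)}")

        payload = {"schema_version": self.schema_version,
                   "experiment": self.experiment,
                   "config": json.loads(self.config.to_json()),
                   "results": self.results,
                   "timings_s": self.timings_s}
        return json.dumps(payload, indent=2, default=default)

    def write(self, out_dir) -> pathlib.Path:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{self.experiment}_report.json"
        path.write_text(self.to_json())
        return path


class _Timer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                timer.timings[name] = round(time.perf_counter() - self.t0, 4)
                log.info("stage %s: %.2fs", name, timer.timings[name])
                return False

        return _Ctx()


def _mode_metrics(config: RunConfig, mode: str) -> dict:
    spec = config.section_spec()
    fields = synthetic.sample_fields(spec)
    section = synthetic.render_section(spec, fields, mode=mode,
                                       lut_size=config.lut_size)
    rng = np.random.default_rng(config.seed + (17 if mode == "nos" else 31))
    healthy = synthetic.sample_region_clouds(section, "healthy",
                                             config.n_regions,
                                             config.region_px, rng)
    cancer = synthetic.sample_region_clouds(section, "cancerous",
                                            config.n_regions,
                                            config.region_px, rng)
    comp = metrics.group_iou_comparison(
        healthy, cancer, grid_size=config.kde_grid_size,
        compute_frobenius=True, compute_chamfer=True)
    return {"comparison": comp,
            "provenance": section.provenance}


def run_comparison_experiment(config: RunConfig) -> RunReport:
    """Healthy-vs-cancer colour separation under NOS vs glass rendering."""
    timer = _Timer()
    if config.dry_run:
        config.section_spec()  # validates
        return RunReport("comparison", config, {"dry_run": True},
                         timer.timings)
    per_mode: dict[str, dict] = {}
    for mode in ("nos", "glass"):
        with timer.stage(f"render+metrics[{mode}]"):
            per_mode[mode] = _mode_metrics(config, mode)
    comp_nos = per_mode["nos"]["comparison"]
    comp_glass = per_mode["glass"]["comparison"]
    with timer.stage("t-test"):
        tt = metrics.ttest_group_ious(comp_nos, comp_glass)
    results = {
        "modes": {
            mode: {
                "iou_matrix": d["comparison"].iou_matrix,
                "mean_iou": d["comparison"].mean_iou,
                "frobenius_matrix": d["comparison"].frobenius_matrix,
                "chamfer_matrix": d["comparison"].chamfer_matrix,
                "kde_bandwidth": d["comparison"].bandwidth,
                "render_provenance": d["provenance"],
            } for mode, d in per_mode.items()},
        "ttest": {"statistic": float(tt.statistic),
                  "pvalue": float(tt.pvalue)},
        "nos_minus_glass_mean_iou": comp_nos.mean_iou - comp_glass.mean_iou,
    }
    report = RunReport("comparison", config, results, timer.timings)
    if config.out_dir:
        _write_comparison_tables(report)
    return report


def _write_comparison_tables(report: RunReport) -> None:
    out = pathlib.Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for mode, d in report.results["modes"].items():
        iou = np.asarray(d["iou_matrix"])
        fro = np.asarray(d["frobenius_matrix"])
        cham = np.asarray(d["chamfer_matrix"])
        for i in range(iou.shape[0]):
            for j in range(iou.shape[1]):
                rows.append({"mode": mode, "healthy_idx": i, "cancer_idx": j,
                             "iou": iou[i, j], "frobenius": fro[i, j],
                             "chamfer_rescaled": cham[i, j]})
    pd.DataFrame(rows).to_csv(out / "pairwise_metrics.csv", index=False)
    report.write(out)


def run_screening_experiment(config: RunConfig) -> RunReport:
    """Tile-level screening: synthesis → baseline classifier → metric suite."""
    timer = _Timer()
    if config.dry_run:
        config.section_spec()
        return RunReport("screening", config, {"dry_run": True},
                         timer.timings)
    base = synthetic.SectionSpec(
        height=config.tile_px * 5, width=config.tile_px * 5,
        layout="healthy", ri_model=dict(config.ri_model),
        thickness_model_um=dict(config.thickness_model_um),
        cavity_thickness_nm=config.cavity_thickness_nm,
        illuminant=config.illuminant, noise_sd=config.noise_sd,
        seed=config.seed)
    with timer.stage("tiles"):
        train, test = synthetic.make_train_test_tiles(
            base, config.n_train_per_class, config.n_test_per_class,
            config.tile_px, seed=config.seed, lut_size=config.lut_size)
    with timer.stage("classifier"):
        scores = synthetic.baseline_tile_classifier(
            train.tiles, train.labels, test.tiles, method=config.classifier)
    with timer.stage("evaluation"):
        pred = (scores >= config.decision_threshold).astype(int)
        y = test.labels
        ev = agreement.BinaryEval(
            tp=int(np.sum((pred == 1) & (y == 1))),
            fp=int(np.sum((pred == 1) & (y == 0))),
            tn=int(np.sum((pred == 0) & (y == 0))),
            fn=int(np.sum((pred == 0) & (y == 1))))
        bm = agreement.binary_metrics(ev)
        cm = agreement.ConfusionMatrix.from_pairs(pred.tolist(), y.tolist(),
                                                  labels=[0, 1])
        kap = agreement.cohens_kappa(cm)
        curve = agreement.roc_curve(scores, y)
        area = agreement.auc(curve)
    results = {
        "confusion": {"tp": ev.tp, "fp": ev.fp, "tn": ev.tn, "fn": ev.fn},
        "accuracy": bm.accuracy, "precision": bm.precision,
        "recall": bm.recall, "f1": bm.f1,
        "undefined_metrics": list(bm.undefined),
        "kappa": kap.kappa, "p0": kap.p0, "pe": kap.pe,
        "auc": area,
        "roc": {"fpr": curve.fpr, "tpr": curve.tpr,
                "thresholds": curve.thresholds},
        "n_train": len(train), "n_test": len(test),
        "train_subjects": sorted(set(train.subjects.tolist())),
        "test_subjects": sorted(set(test.subjects.tolist())),
    }
    report = RunReport("screening", config, results, timer.timings)
    if config.out_dir:
        report.write(config.out_dir)
    return report
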
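"""End-to-end orchestration: simulate -> train -> evaluate.

The synthetic benchmark mirrors a four-test-set design: two water
backgrounds (drinking, river) crossed with two mixture designs (a "full"
set with all five targets at varied ratios, and a "sparse" set with
exactly two targets at equal concentrations), 39 test samples in total.
Thresholds are always fitted on validation scores, never on test data.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from . import quantify as Q
from .mixtures import DATASET_SIZES, DEFAULT_SCALE_RANGE, SimDataset, generate_dataset
from .models import (
    ArchitectureConfig,
    TrainedModel,
    TrainingConfig,
    build_model,
    predict_scores,
    train,
)
from .references import (
    DEFAULT_RESPONSE_MODELS,
    TARGETS,
    NoiseConfig,
    ResponseModel,
    default_reference_library,
    ratio_to_concentrations,
    simulate_measured_spectrum,
)
from .spectra import Spectrum, SpectrumSet, WavenumberGrid, max_normalize

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "TestSet",
    "build_library",
    "fit_calibration_curves",
    "run_simulate",
    "run_train",
    "make_test_sets",
    "run_evaluate",
    "run_demo",
]

log = logging.getLogger("pahsers")

TEST_SET_NAMES = ("drinking-full", "drinking-sparse", "river-full", "river-sparse")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every knob of the synthetic benchmark, with explicit per-stage seeds."""

    # spectral grid
    grid_start: float = 400.0
    grid_end: float = 2000.0
    n_points: int = 660

    # measurement model
    noise_sd: float = 0.01
    max_shift: int = 2
    background_scale: float = 0.05

    # simulator (contribution zeroing and floor, signal scale range)
    zero_prob: float = 0.2
    min_frac: float = 0.01
    scale_range: tuple[float, float] = DEFAULT_SCALE_RANGE
    n_train: int = DATASET_SIZES["train"]
    n_validation: int = DATASET_SIZES["validation"]
    n_optimization: int = DATASET_SIZES["optimization"]

    # models
    dense_units: int = 64
    dropout: float = 0.2
    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 9, 2), (16, 9, 2), (32, 9, 2))
    max_epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 4

    # calibration and test design
    calibration_concs: tuple[float, ...] = (0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)
    sparse_conc: float = 0.5       # uM per target in sparse test sets
    full_total_conc: float = 1.0   # uM total across the five targets in full sets
    test_counts: tuple[int, int, int, int] = (10, 10, 10, 9)  # 39 samples total

    # per-stage seeds
    seed: int = 1

    def stage_seed(self, stage: str) -> int:
        offsets = {"train": 11, "validation": 23, "optimization": 37,
                   "classifier": 41, "regressor": 53, "test": 67, "tune": 79}
        return (self.seed * 1_000 + offsets[stage]) % (2**31 - 1)

    @property
    def grid(self) -> WavenumberGrid:
        return WavenumberGrid(self.grid_start, self.grid_end, self.n_points)

    def noise(self, seed_offset: int = 0) -> NoiseConfig:
        return NoiseConfig(self.noise_sd, self.max_shift, self.background_scale,
                           seed=self.seed + seed_offset)

    def training(self, stage: str) -> TrainingConfig:
        return TrainingConfig(self.max_epochs, self.batch_size, self.learning_rate,
                              self.patience, seed=self.stage_seed(stage))

    def architecture(self, head: str) -> ArchitectureConfig:
        return ArchitectureConfig(self.conv_blocks, self.dense_units, self.dropout, head)

    def smoke(self) -> "PipelineConfig":
        """Scaled-down copy for fast pipeline checks."""
        cfg = PipelineConfig(**{**asdict(self)})
        cfg.conv_blocks = tuple(tuple(b) for b in cfg.conv_blocks)
        cfg.scale_range = tuple(cfg.scale_range)
        cfg.calibration_concs = tuple(cfg.calibration_concs)
        cfg.test_counts = tuple(cfg.test_counts)
        cfg.n_train, cfg.n_validation, cfg.n_optimization = 400, 120, 200
        cfg.max_epochs, cfg.patience = 6, 5
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale_range"] = list(d["scale_range"])
        d["conv_blocks"] = [list(b) for b in d["conv_blocks"]]
        d["calibration_concs"] = list(d["calibration_concs"])
        d["test_counts"] = list(d["test_counts"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scale_range" in d:
            d["scale_range"] = tuple(d["scale_range"])
        if "conv_blocks" in d:
            d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        if "calibration_concs" in d:
            d["calibration_concs"] = tuple(d["calibration_concs"])
        if "test_counts" in d:
            d["test_counts"] = tuple(d["test_counts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def build_library(config: PipelineConfig) -> SpectrumSet:
    return default_reference_library(config.grid, config.background_scale)


def fit_calibration_curves(
    refs: SpectrumSet,
    responses: dict[str, ResponseModel] | None = None,
    concs: tuple[float, ...] = PipelineConfig().calibration_concs,
) -> dict[str, Q.CalibrationCurve]:
    """Calibrate each target from noiseless single-target simulations.

    The characteristic peak height of a single-target spectrum (background
    and noise off) at concentration c is exactly the response height, so
    the Hill fit recovers the response model to numerical precision.
    """
    responses = responses or DEFAULT_RESPONSE_MODELS
    silent = NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.0)
    curves = {}
    for t in TARGETS:
        heights = []
        for c in concs:
            s = simulate_measured_spectrum({t: c}, responses, refs, silent)
            heights.append(s.max)
        curves[t] = Q.fit_calibration_curve(np.array(concs), np.array(heights),
                                            form="hill", target=t)
    return curves


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("%s finished in %.1f s", stage, time.perf_counter() - self.t0)

    return _Timer()


def run_simulate(config: PipelineConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Generate reference library + train/validation/optimization datasets."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "simulate.json"
    if marker.exists() and not force:
        raise PipelineError(f"{marker} exists; pass force=True / --force to overwrite")
    refs = build_library(config)
    refs.save(out / "references")
    sizes = {"train": config.n_train, "validation": config.n_validation,
             "optimization": config.n_optimization}
    for role, n in sizes.items():
        with _timed(f"simulate {role} (n={n})"):
            ds = generate_dataset(
                n, role, refs, config.noise(), seed=config.stage_seed(role),
                zero_prob=config.zero_prob, min_frac=config.min_frac,
                scale_range=config.scale_range,
            )
            ds.save(out / role)
    meta = {"config": config.to_dict(), "config_hash": config.config_hash, "sizes": sizes}
    marker.write_text(json.dumps(meta, indent=1))
    return meta


def _check_hash(meta_path: Path, config: PipelineConfig) -> None:
    meta = json.loads(meta_path.read_text())
    if meta.get("config_hash") != config.config_hash:
        raise PipelineError(
            f"config hash mismatch: {meta_path} was produced with "
            f"{meta.get('config_hash')}, current config is {config.config_hash}"
        )


def run_train(config: PipelineConfig, data_dir: str | Path, out_dir: str | Path) -> dict:
    """Train classifier + regressor, fit validation thresholds and calibrations."""
    data, out = Path(data_dir), Path(out_dir)
    if not (data / "simulate.json").exists():
        raise PipelineError(f"no simulated datasets under {data}; run simulate first")
    _check_hash(data / "simulate.json", config)
    out.mkdir(parents=True, exist_ok=True)
    train_set = SimDataset.load(data / "train")
    val_set = SimDataset.load(data / "validation")
    refs = SpectrumSet.load(data / "references")

    models = {}
    for head in ("classifier", "regressor"):
        with _timed(f"train {head}"):
            model = build_model(config.architecture(head), config.n_points,
                                seed=config.stage_seed(head))
            model = train(model, train_set, val_set, config.training(head))
            model.save(out / f"{head}.npz")
            models[head] = model

    val_scores = predict_scores(models["classifier"], val_set)
    thresholds = Q.ThresholdSet.fit(val_scores, val_set.presence)
    thresholds.save(out / "thresholds.json")

    curves = fit_calibration_curves(refs, concs=config.calibration_concs)
    (out / "calibration.json").write_text(
        json.dumps({t: c.to_dict() for t, c in curves.items()}, indent=1)
    )
    meta = {
        "config_hash": config.config_hash,
        "history": {h: models[h].history for h in models},
        "thresholds": thresholds.thresholds.tolist(),
        "geometric_means": thresholds.geometric_means.tolist(),
    }
    (out / "train.json").write_text(json.dumps(meta, indent=1))
    return meta


@dataclass
class TestSet:
    """One synthetic test set with ground truth."""

    name: str
    X: np.ndarray            # (n, w) unit-max model inputs
    raw_max: np.ndarray      # (n,)
    presence: np.ndarray     # (n, 5)
    concentrations: np.ndarray  # (n, 5) uM
    true_labels: np.ndarray  # (n, 6) oracle contributions + z


def _true_labels(heights: np.ndarray, raw_max: float) -> np.ndarray:
    """Oracle 6-vector for a sample with known per-target absolute heights."""
    S = heights.sum()
    if S <= 0:
        return np.zeros(6)
    contribs = heights / S
    return np.append(contribs, raw_max / S)


def make_test_sets(
    config: PipelineConfig,
    refs: SpectrumSet,
    responses: dict[str, ResponseModel] | None = None,
    seed: int | None = None,
) -> list[TestSet]:
    """The four synthetic test sets (2 backgrounds x {full, sparse})."""
    responses = responses or DEFAULT_RESPONSE_MODELS
    seed = config.stage_seed("test") if seed is None else seed
    rng = np.random.default_rng(seed)
    base_ratio = np.array([5.0, 2.0, 1.0, 1.0, 1.0])
    pair_cycle = list(itertools.combinations(range(5), 2))
    sets = []
    for name, count in zip(TEST_SET_NAMES, config.test_counts):
        preset = "river" if name.startswith("river") else "drinking"
        X = np.empty((count, config.n_points))
        raw_max = np.empty(count)
        presence = np.zeros((count, 5), dtype=int)
        concs = np.zeros((count, 5))
        labels = np.zeros((count, 6))
        for i in range(count):
            if name.endswith("full"):
                ratio = np.roll(base_ratio, i % 5)
                c = ratio_to_concentrations(config.full_total_conc, ratio)
            else:
                c = np.zeros(5)
                pair = pair_cycle[i % len(pair_cycle)]
                c[list(pair)] = config.sparse_conc
            cfg = NoiseConfig(config.noise_sd, config.max_shift,
                              config.background_scale, seed=seed)
            spec = simulate_measured_spectrum(
                {t: c[j] for j, t in enumerate(TARGETS)},
                responses, refs, cfg, preset=preset, rng=rng,
                label=f"{name}-{i}",
            )
            normed, mx = max_normalize(spec)
            heights = np.array([responses[t].height(c[j]) for j, t in enumerate(TARGETS)])
            X[i] = normed.intensities
            raw_max[i] = mx
            presence[i] = (c > 0).astype(int)
            concs[i] = c
            labels[i] = _true_labels(heights, mx)
        sets.append(TestSet(name, X, raw_max, presence, concs, labels))
    return sets


def _metrics_block(calls: np.ndarray, presence: np.ndarray) -> dict:
    cms = [M.confusion(calls[:, j], presence[:, j]) for j in range(5)]
    micro, macro, warnings = M.micro_macro(cms)
    return {
        "per_target": {
            t: {**M.class_metrics(cm).as_dict(),
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
            for t, cm in zip(TARGETS, cms)
        },
        "micro": micro.as_dict(),
        "macro": macro.as_dict(),
        "macro_warnings": warnings,
        "subset_accuracy": M.subset_accuracy(calls, presence),
        "per_call_accuracy": M.per_call_accuracy(calls, presence),
    }


def evaluate_test_set(
    ts: TestSet,
    classifier: TrainedModel | None,
    regressor: TrainedModel | None,
    thresholds: Q.ThresholdSet,
    curves: dict[str, Q.CalibrationCurve],
    refs: SpectrumSet,
    oracle: bool = False,
) -> dict:
    """Classification + quantification report for one test set.

    ``oracle=True`` substitutes the ground-truth labels for both model
    outputs (the ceiling any trained model is compared against).
    """
    if oracle:
        cls_scores = ts.presence.astype(float)
        reg_scores = ts.true_labels
    else:
        cls_scores = predict_scores(classifier, ts.X)
        reg_scores = predict_scores(regressor, ts.X)
    calls = Q.classify(cls_scores, thresholds)
    block = _metrics_block(calls, ts.presence)

    pred_concs = np.zeros_like(ts.concentrations)
    flags = np.zeros_like(ts.presence, dtype=bool)
    recon = np.zeros_like(ts.X)
    for i in range(len(ts.X)):
        qr = Q.contributions_to_concentrations(reg_scores[i], float(ts.raw_max[i]), curves)
        pred_concs[i] = qr.concentrations
        flags[i] = qr.extrapolated
        recon[i] = M.reconstruct_predicted_spectrum(
            reg_scores[i], refs, float(ts.raw_max[i]), normalize=True
        ).intensities
    report = {
        "name": ts.name,
        "n": len(ts.X),
        "classification": block,
        "rmse_spectrum": M.rmse_spectrum(recon, ts.X),
        "rmse_conc": M.rmse_conc(pred_concs, ts.concentrations),
        "extrapolation_flags": int(flags.sum()),
        "pred_concentrations": pred_concs.tolist(),
        "true_concentrations": ts.concentrations.tolist(),
    }
    # ROC only when every target has both classes in this set
    both = all(0 < ts.presence[:, j].sum() < len(ts.X) for j in range(5))
    if both and not oracle:
        micro_roc, macro_auc, per = M.roc_micro_macro(cls_scores, ts.presence)
        report["auc"] = {
            "micro": micro_roc.auc,
            "macro": macro_auc,
            "per_target": {t: r.auc for t, r in zip(TARGETS, per)},
        }
    return report


def run_evaluate(
    config: PipelineConfig,
    data_dir: str | Path,
    model_dir: str | Path,
    out_dir: str | Path,
    oracle: bool = False,
) -> dict:
    """Evaluate both models on the four synthetic test sets plus combined."""
    data, mdir, out = Path(data_dir), Path(model_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = SpectrumSet.load(data / "references")
    if oracle:
        # ground-truth labels stand in for both models; any mid-range cutoff works
        classifier = regressor = None
        thresholds = Q.ThresholdSet(np.full(5, 0.5), np.ones(5))
        curves = fit_calibration_curves(refs, concs=config.calibration_concs)
    else:
        for needed in ("classifier.npz", "regressor.npz", "thresholds.json", "calibration.json"):
            if not (mdir / needed).exists():
                raise PipelineError(f"missing {mdir / needed}; run train first")
        _check_hash(mdir / "train.json", config)
        classifier = TrainedModel.load(mdir / "classifier.npz")
        regressor = TrainedModel.load(mdir / "regressor.npz")
        thresholds = Q.ThresholdSet.load(mdir / "thresholds.json")
        curves = {
            t: Q.CalibrationCurve.from_dict(d)
            for t, d in json.loads((mdir / "calibration.json").read_text()).items()
        }
    sets = make_test_sets(config, refs)
    reports = {}
    for ts in sets:
        with _timed(f"evaluate {ts.name} (n={len(ts.X)})"):
            reports[ts.name] = evaluate_test_set(
                ts, classifier, regressor, thresholds, curves, refs, oracle=oracle
            )

    # combined report over all 39 samples
    all_X = np.vstack([ts.X for ts in sets])
    combined = TestSet(
        "combined",
        all_X,
        np.concatenate([ts.raw_max for ts in sets]),
        np.vstack([ts.presence for ts in sets]),
        np.vstack([ts.concentrations for ts in sets]),
        np.vstack([ts.true_labels for ts in sets]),
    )
    reports["combined"] = evaluate_test_set(
        combined, classifier, regressor, thresholds, curves, refs, oracle=oracle
    )
    result = {"config_hash": config.config_hash, "oracle": oracle, "reports": reports}
    (out / "evaluation.json").write_text(json.dumps(result, indent=1))
    _write_tables(reports, out)
    return result


def _write_tables(reports: dict, out: Path) -> None:
    """Human-readable metric table + per-sample concentration CSV."""
    rows = []
    for name, rep in reports.items():
        cls = rep["classification"]
        rows.append({
            "test_set": name,
            "n": rep["n"],
            "micro_precision": cls["micro"]["precision"],
            "micro_f1": cls["micro"]["f1"],
            "macro_f1": cls["macro"]["f1"],
            "subset_accuracy": cls["subset_accuracy"],
            "per_call_accuracy": cls["per_call_accuracy"],
            "auc_micro": rep.get("auc", {}).get("micro"),
            "auc_macro": rep.get("auc", {}).get("macro"),
            "rmse_spectrum": rep["rmse_spectrum"],
            "rmse_conc": rep["rmse_conc"],
        })
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    conc_rows = []
    for name, rep in reports.items():
        if name == "combined":
            continue
        for i, (p, a) in enumerate(zip(rep["pred_concentrations"], rep["true_concentrations"])):
            row = {"test_set": name, "sample": i}
            for j, t in enumerate(TARGETS):
                row[f"pred_{t}"] = p[j]
                row[f"true_{t}"] = a[j]
            conc_rows.append(row)
    pd.DataFrame(conc_rows).to_csv(out / "concentrations.csv", index=False)


def run_demo(out_dir: str | Path, seed: int = 1) -> dict:
    """Small end-to-end run (smoke-sized) writing all artifacts under out_dir."""
    config = PipelineConfig(seed=seed).smoke()
    out = Path(out_dir)
    run_simulate(config, out / "data", force=True)
    run_train(config, out / "data", out / "models")
    return run_evaluate(config, out / "data", out / "models", out / "reports")
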
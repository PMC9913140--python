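"""End-to-end orchestration: preprocess -> tune/extract -> DBN -> reports.

The run proceeds in the staged order of the method: every image is median
filtered and contrast enhanced, resized to the extractor input; the
metaheuristic tunes the extractor's training hyperparameters against the
validation error rate; the tuned extractor maps images to feature vectors;
a DBN is pretrained and fine-tuned (Adamax) on the training partition of
each requested split ratio; and each split yields training-phase and
testing-phase evaluation reports plus confusion matrices, per-epoch
traces, and raw scores for ROC/PR export.

Randomness flows from one root seed through named substreams (data,
splits, tuning, extractor, dbn), so changing the consumer of one stream
does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import resize

from . import aoa, dbn, metrics, preprocess, squeezenet, synthetic
from .errors import ParameterError

__all__ = ["RunConfig", "RunResult", "run_experiment", "load_config", "substream"]

# fixed substream names -> SeedSequence spawn indices
_STREAMS = ("data", "split", "tune", "extractor", "dbn")


def substream(root_seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the root seed."""
    if name not in _STREAMS:
        raise ParameterError(f"unknown substream {name!r}; choose from {_STREAMS}")
    ss = np.random.SeedSequence([root_seed, _STREAMS.index(name)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one experiment.

    Desk-scale defaults: 32x32 extractor input, metaheuristic budget
    population 10 x 10 iterations with 5-epoch fitness evaluations, DBN
    pretraining 10 epochs and fine-tuning 30 epochs (batch 5, learning
    rate 0.01, dropout 0.5).  ``full_scale=True`` raises the DBN budget to
    the reference settings (50 epochs).
    """

    # data: either a directory with images + labels.csv, or a synthetic recipe
    data_dir: str | None = None
    magnification: str = "100x"
    scale: float = 0.1
    preset: str = "easy"
    image_size: int = 64

    # preprocessing
    median_window: int = 3
    contrast: str = "clahe"
    clip_limit: float = 0.01
    tile: int = 8

    # extractor + tuning
    extractor_input: int = 32
    tune_population: int = 10
    tune_iterations: int = 10
    tune_epochs: int = 5          # extractor epochs per fitness evaluation
    final_epochs: int = 10        # extractor epochs for the final training
    tune: bool = True

    # dbn
    hidden_sizes: tuple[int, ...] = (64, 32)
    pretrain_epochs: int = 10
    finetune_epochs: int = 30
    batch_size: int = 5
    learning_rate: float = 0.01
    dropout: float = 0.5
    full_scale: bool = False

    splits: tuple[str, ...] = ("80:20", "70:30")
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        for r in self.splits:
            if r not in ("80:20", "70:30"):
                raise ParameterError(f"unsupported split ratio {r!r}")
        if self.preset not in ("easy", "hard"):
            raise ParameterError(f"preset must be 'easy' or 'hard', got {self.preset!r}")
        if self.tune_population < 2 or self.tune_iterations < 1:
            raise ParameterError("tuning budget too small")

    @property
    def dbn_epochs(self) -> tuple[int, int]:
        if self.full_scale:
            return 50, 50
        return self.pretrain_epochs, self.finetune_epochs

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration into a validated RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    for key in ("hidden_sizes", "splits"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass
class RunResult:
    reports: dict[str, dict[str, metrics.EvalReport]]   # ratio -> phase -> report
    confusions: dict[str, dict[str, metrics.ConfusionMatrix]]
    traces: dict[str, list[dict]]                        # ratio -> finetune log
    scores: dict[str, dict[str, np.ndarray]]             # ratio -> phase -> scores
    best_hyperparams: dict | None
    tuning_log: list | None
    config: RunConfig


def _load_directory(data_dir: str):
    from PIL import Image

    root = Path(data_dir)
    labels_csv = root / "labels.csv"
    if not labels_csv.exists():
        raise ParameterError(f"no labels.csv under {data_dir}")
    images, labels = [], []
    for line in labels_csv.read_text().strip().splitlines()[1:]:
        path, label = line.rsplit(",", 1)
        if label not in synthetic.LABELS:
            raise ParameterError(f"label {label!r} not in {sorted(synthetic.LABELS)}")
        images.append(np.asarray(Image.open(root / path)))
        labels.append(synthetic.LABELS[label])
    return images, np.asarray(labels, dtype=np.int64)


def _prepare_images(config: RunConfig):
    """Load or synthesize, preprocess, and resize to the extractor input."""
    if config.data_dir:
        images, labels = _load_directory(config.data_dir)
    else:
        ds = synthetic.make_breakhis_like(
            config.magnification, config.scale,
            seed=substream(config.seed, "data"),
            size=config.image_size, preset=config.preset,
        )
        images, labels = ds.images, ds.labels
    side = config.extractor_input
    processed = []
    for img in images:
        clean = preprocess.preprocess_image(
            img, config.median_window, config.contrast,
            config.clip_limit, config.tile, grayscale=True,
        )
        small = resize(clean.astype(np.float64) / 255.0, (side, side),
                       order=1, anti_aliasing=True, preserve_range=True)
        processed.append(small)
    return processed, labels


def _default_search_space():
    # extractor training hyperparameters; learning rate on a log10 scale
    return [
        aoa.SearchDimension("learning_rate", "log", -3.0, -1.0),
        aoa.SearchDimension("epochs", "int", 2, 8),
        aoa.SearchDimension("batch_size", "cat", choices=(8, 16, 32)),
    ]


def _tune_extractor(images, labels, ext_config, config: RunConfig):
    """Metaheuristic search of extractor training hyperparameters.

    Fitness of a candidate: train extractor + temporary head briefly on an
    inner 80/20 split of the training partition, return the validation
    error rate in percent.  Deterministic per position (fixed inner split
    and training seed).
    """
    tune_seed = substream(config.seed, "tune")
    tr, va = metrics.split_dataset(labels, "80:20", seed=tune_seed)
    tr_imgs = [images[i] for i in tr]
    va_imgs = [images[i] for i in va]

    def objective(params: dict) -> float:
        weights, _, head = squeezenet.train_extractor(
            tr_imgs, labels[tr], ext_config,
            epochs=min(params["epochs"], config.tune_epochs),
            lr=params["learning_rate"], batch_size=params["batch_size"],
            seed=tune_seed, return_head=True,
        )
        feats_va = squeezenet.extract_features(va_imgs, ext_config, weights)
        preds = (feats_va @ head[0] + head[1]).argmax(axis=1)
        return aoa.fitness_error_rate(preds, labels[va])

    best, best_fit, log = aoa.tune_hyperparameters(
        _default_search_space(), objective,
        population=config.tune_population,
        max_iterations=config.tune_iterations,
        seed=tune_seed,
    )
    return best, best_fit, log


def _evaluate_split(features, labels, ratio: str, config: RunConfig):
    split_seed = substream(config.seed, "split")
    dbn_seed = substream(config.seed, "dbn")
    tr, te = metrics.split_dataset(labels, ratio, seed=split_seed)
    pre_epochs, fine_epochs = config.dbn_epochs

    layer_sizes = [features.shape[1], *config.hidden_sizes]
    model = dbn.build_model(layer_sizes, n_classes=2, seed=dbn_seed)
    x_tr = dbn.scale_features(model, features[tr], fit=True)
    x_te = dbn.scale_features(model, features[te])

    pre_cfg = dbn.TrainConfig(epochs=pre_epochs, batch_size=config.batch_size,
                              learning_rate=config.learning_rate,
                              dropout=config.dropout, seed=dbn_seed)
    fine_cfg = dataclasses.replace(pre_cfg, epochs=fine_epochs)
    model = dbn.greedy_pretrain(model, x_tr, pre_cfg)
    log: list[dict] = []
    model = dbn.up_down_finetune(model, x_tr, labels[tr], fine_cfg, log=log)

    out_reports, out_cms, out_scores = {}, {}, {}
    for phase, idx, x in (("training", tr, x_tr), ("testing", te, x_te)):
        preds, scores = dbn.predict(model, x, scaled=True)
        cm = metrics.confusion_from_labels(labels[idx], preds)
        out_reports[phase] = metrics.compute_report(cm, split=ratio, phase=phase)
        out_cms[phase] = cm
        out_scores[phase] = scores
    return out_reports, out_cms, out_scores, log, (tr, te)


def run_experiment(config: RunConfig) -> RunResult:
    """Execute the full pipeline and (optionally) write artifacts.

    Returns per-split training/testing reports; identical config + seed
    gives identical results.  Any stage failure is re-raised with the
    stage name and config hash attached.
    """
    stage = "prepare"
    try:
        images, labels = _prepare_images(config)

        stage = "tune"
        ext_config = squeezenet.ExtractorConfig(
            input_size=(config.extractor_input, config.extractor_input, 1),
            seed=substream(config.seed, "extractor"),
        )
        best_params, tuning_log = None, None
        train_kwargs = dict(epochs=config.final_epochs,
                            lr=config.learning_rate, batch_size=16)
        if config.tune:
            best_params, _fit, tuning_log = _tune_extractor(
                images, labels, ext_config, config)
            train_kwargs = dict(epochs=config.final_epochs,
                                lr=best_params["learning_rate"],
                                batch_size=best_params["batch_size"])

        stage = "extract"
        weights, _losses = squeezenet.train_extractor(
            images, labels, ext_config, seed=substream(config.seed, "extractor"),
            **train_kwargs)
        features = squeezenet.extract_features(images, ext_config, weights)

        stage = "classify"
        reports, confusions, traces, scores = {}, {}, {}, {}
        for ratio in config.splits:
            rep, cms, sc, log, _ = _evaluate_split(features, labels, ratio, config)
            reports[ratio] = rep
            confusions[ratio] = cms
            scores[ratio] = sc
            traces[ratio] = log

        result = RunResult(reports, confusions, traces, scores,
                           best_params, tuning_log, config)
        if config.out_dir:
            stage = "write"
            _write_artifacts(result)
        return result
    except Exception as exc:
        raise type(exc)(
            f"[stage={stage} config={config.config_hash()}] {exc}"
        ) from exc


def _write_artifacts(result: RunResult) -> None:
    import pandas as pd

    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    with open(log_path, "w") as fh:
        fh.write(json.dumps({"config_hash": result.config.config_hash(),
                             "seed": result.config.seed,
                             "time": time.strftime("%Y-%m-%dT%H:%M:%S")}) + "\n")
        if result.best_hyperparams:
            fh.write(json.dumps({"best_hyperparams": result.best_hyperparams}) + "\n")
    md_blocks = []
    for ratio, phases in result.reports.items():
        tag = ratio.replace(":", "-")
        for phase, report in phases.items():
            report.to_frame().to_csv(out / f"report_{tag}_{phase}.csv")
            md_blocks.append(f"### Training/Testing ({ratio}) — {phase} phase\n\n"
                             + report.to_markdown())
            cm = result.confusions[ratio][phase]
            pd.DataFrame(cm.counts, index=["benign", "malignant"],
                         columns=["pred_benign", "pred_malignant"]).to_csv(
                out / f"confusion_{tag}_{phase}.csv")
            np.savetxt(out / f"scores_{tag}_{phase}.csv",
                       result.scores[ratio][phase], delimiter=",",
                       header="score_benign,score_malignant", comments="")
        if result.traces.get(ratio):
            pd.DataFrame([r for r in result.traces[ratio] if "epoch" in r]).to_csv(
                out / f"finetune_trace_{tag}.csv", index=False)
    (out / "reports.md").write_text("\n\n".join(md_blocks) + "\n")
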
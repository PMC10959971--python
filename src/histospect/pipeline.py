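"""Pipeline orchestration: prepare -> extract -> reduce -> fuse -> select ->
train -> evaluate, driven by a single validated configuration.

Four experiment presets stage the analysis:

* ``exp1`` — end-to-end CNN classification: fine-tune each backbone's
  replacement head and score the test tiles with it.
* ``exp2`` — raw deep features from each backbone into a shallow classifier.
* ``exp3`` — per-backbone DCT reduction before the classifier.
* ``exp4`` — spectral fusion of all backbones' features (and ANOVA top-k
  selection on the fused or concatenated features) before the classifier;
  one report per ``k`` in the configured grid plus the fusion-only report.

Every run writes intermediate feature CSVs with JSON sidecars, evaluation
reports, a timestamped log and a manifest (config echo, fanned-out seeds,
artifact SHA-256 hashes) from which the run is reproducible.
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

from . import __version__
from .anova import anova_f_scores, apply_selection, select_top_k
from .backbones import (BackboneSpec, TrainConfig, build_backbone,
                        extract_features, finetune_backbone,
                        CNN_ARCHITECTURES)
from .classify import (CubicSvmSpec, EsdSpec, predict, train_cubic_svm,
                       train_esd)
from .dataset import (AugmentConfig, SplitSpec, augment_training_set,
                      export_split_csv, load_image_dataset,
                      resize_for_backbone, stratified_split)
from .evaluate import EvaluationReport, evaluate_predictions
from .features import FeatureMatrix
from .spectral import SpectralConfig, fuse_features_dct, reduce_features_dct
from .synthetic import TextureDatasetSpec, generate_texture_dataset

__all__ = ["PipelineConfig", "PipelineError", "validate_config",
           "config_from_dict", "run_pipeline", "desk_config"]

#: Default retained-coefficient counts for the per-backbone DCT reduction.
DEFAULT_REDUCE_KEEP = {"alexnet": 1500, "resnet50": 1200, "densenet201": 1000}
DEFAULT_FUSION_KEEP = 4000
DEFAULT_ANOVA_GRID = [1000, 1500, 2000, 2500]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline description."""

    dataset: dict
    backbones: list[dict]
    classifier: dict
    split: SplitSpec = field(default_factory=SplitSpec)
    augment: AugmentConfig | None = None
    reduce_keep: dict | list = field(default_factory=dict)  # name -> N_keep, or per-backbone list
    spectral_mode: str = "one_d"
    fusion_keep: int = DEFAULT_FUSION_KEEP
    anova_grid: list[int] = field(default_factory=lambda: list(DEFAULT_ANOVA_GRID))
    anova_input: str = "concat"  # "concat" | "fused"
    train: TrainConfig = field(default_factory=TrainConfig)
    output_dir: str = "histospect_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "dataset": self.dataset,
            "backbones": self.backbones,
            "classifier": self.classifier,
            "split": dataclasses.asdict(self.split),
            "augment": dataclasses.asdict(self.augment) if self.augment else None,
            "reduce": {"keep": self.reduce_keep, "mode": self.spectral_mode},
            "fusion": {"n_coefficients": self.fusion_keep},
            "anova": {"k_grid": self.anova_grid, "input": self.anova_input},
            "train": dataclasses.asdict(self.train),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        return d


_TOP_KEYS = {"dataset", "backbones", "classifier", "split", "augment", "reduce",
             "fusion", "anova", "train", "output_dir", "seed"}
_SECTION_KEYS = {
    "dataset": {"root", "synthetic"},
    "split": {"train_fraction", "seed", "stratified"},
    "augment": {"horizontal_flip", "vertical_flip", "rotation_range_degrees",
                "copies_per_image", "seed"},
    "reduce": {"keep", "mode"},
    "fusion": {"n_coefficients", "mode"},
    "anova": {"k_grid", "k", "input"},
    "train": {"minibatch_size", "learning_rate", "max_epochs", "optimizer",
              "momentum", "validation_fraction", "n_output_classes"},
    "classifier": {"kind", "C", "coef0", "kernel_scale", "standardize",
                   "n_learners", "subspace_dim", "shrinkage", "seed"},
}
_SYNTH_KEYS = {"n_classes", "per_class", "tile_size", "orientations",
               "frequencies", "noise_sd", "seed"}
_BACKBONE_KEYS = {"name", "weights_mode", "expected_dim", "finetune"}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    for key in given:
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in section {section!r}")


def config_from_dict(raw: dict) -> PipelineConfig:
    """Validate a raw mapping and fill every default."""
    _check_keys("<top level>", raw, _TOP_KEYS)
    if "dataset" not in raw:
        raise ValueError("config requires a 'dataset' section")
    if "classifier" not in raw:
        raise ValueError("config requires a 'classifier' section")

    seed = int(raw.get("seed", 0))

    dataset = dict(raw["dataset"])
    _check_keys("dataset", dataset, _SECTION_KEYS["dataset"])
    if ("root" in dataset) == ("synthetic" in dataset):
        raise ValueError("dataset needs exactly one of 'root' or 'synthetic'")
    if "synthetic" in dataset:
        synth = dict(dataset["synthetic"])
        _check_keys("dataset.synthetic", synth, _SYNTH_KEYS)
        synth.setdefault("seed", seed)
        TextureDatasetSpec(**synth)  # validate eagerly
        dataset["synthetic"] = synth

    # Stage seeds fan out from the global seed unless set explicitly.
    split_raw = dict(raw.get("split", {}))
    _check_keys("split", split_raw, _SECTION_KEYS["split"])
    split_raw.setdefault("seed", seed + 1)
    split = SplitSpec(**split_raw)

    augment = None
    if raw.get("augment") is not None:
        aug_raw = dict(raw["augment"])
        _check_keys("augment", aug_raw, _SECTION_KEYS["augment"])
        if "rotation_range_degrees" in aug_raw:
            aug_raw["rotation_range_degrees"] = tuple(
                aug_raw["rotation_range_degrees"])
        aug_raw.setdefault("seed", seed + 2)
        augment = AugmentConfig(**aug_raw)

    backbones_raw = raw.get("backbones") or [{"name": "alexnet"},
                                             {"name": "resnet50"},
                                             {"name": "densenet201"}]
    backbones = []
    for b in backbones_raw:
        if isinstance(b, str):
            b = {"name": b}
        b = dict(b)
        _check_keys("backbones[]", b, _BACKBONE_KEYS)
        spec_kwargs = {k: v for k, v in b.items() if k != "finetune"}
        BackboneSpec(**spec_kwargs)  # validate eagerly
        backbones.append(b)

    reduce_raw = dict(raw.get("reduce", {}))
    _check_keys("reduce", reduce_raw, _SECTION_KEYS["reduce"])
    reduce_keep = reduce_raw.get("keep", {})
    if isinstance(reduce_keep, dict):
        reduce_keep = dict(reduce_keep)
    else:
        reduce_keep = [int(k) for k in reduce_keep]
        if len(reduce_keep) != len(raw.get("backbones") or [1, 2, 3]):
            raise ValueError("reduce.keep list must align with backbones")
    mode = reduce_raw.get("mode", "one_d")

    fusion_raw = dict(raw.get("fusion", {}))
    _check_keys("fusion", fusion_raw, _SECTION_KEYS["fusion"])
    fusion_keep = int(fusion_raw.get("n_coefficients", DEFAULT_FUSION_KEEP))

    anova_raw = dict(raw.get("anova", {}))
    _check_keys("anova", anova_raw, _SECTION_KEYS["anova"])
    if "k" in anova_raw and "k_grid" in anova_raw:
        raise ValueError("anova takes 'k' or 'k_grid', not both")
    grid = ([int(anova_raw["k"])] if "k" in anova_raw
            else [int(k) for k in anova_raw.get("k_grid", DEFAULT_ANOVA_GRID)])
    anova_input = anova_raw.get("input", "concat")
    if anova_input not in ("concat", "fused"):
        raise ValueError("anova.input must be 'concat' or 'fused'")

    train_raw = dict(raw.get("train", {}))
    _check_keys("train", train_raw, _SECTION_KEYS["train"])
    train = TrainConfig(**train_raw)

    classifier = dict(raw["classifier"])
    _check_keys("classifier", classifier, _SECTION_KEYS["classifier"])
    kind = classifier.get("kind")
    if kind not in ("cubic_svm", "esd"):
        raise ValueError("classifier.kind must be 'cubic_svm' or 'esd'")

    return PipelineConfig(
        dataset=dataset, backbones=backbones, classifier=classifier,
        split=split, augment=augment, reduce_keep=reduce_keep,
        spectral_mode=mode, fusion_keep=fusion_keep, anova_grid=grid,
        anova_input=anova_input, train=train,
        output_dir=str(raw.get("output_dir", "histospect_run")),
        seed=int(raw.get("seed", 0)),
    )


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON) config file and normalize it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not hold a mapping")
    return config_from_dict(raw)


# ----------------------------------------------------------------- running
def _classifier_for(cfg: PipelineConfig, seed: int):
    c = dict(cfg.classifier)
    kind = c.pop("kind")
    if kind == "cubic_svm":
        return kind, CubicSvmSpec(**c)
    c.setdefault("seed", seed)
    return kind, EsdSpec(**c)


def _fit_eval(kind, spec, Ftr: FeatureMatrix, Fte: FeatureMatrix,
              class_names) -> EvaluationReport:
    model = (train_cubic_svm(Ftr, spec) if kind == "cubic_svm"
             else train_esd(Ftr, spec))
    labels, scores = predict(model, Fte)
    return evaluate_predictions(Fte.labels, labels, class_names, scores)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_keep(name: str, width: int) -> int:
    return min(DEFAULT_REDUCE_KEEP.get(name, max(width // 2, 1)), width)


def run_pipeline(cfg: PipelineConfig, experiment: str = "exp4"
                 ) -> dict[str, EvaluationReport]:
    """Execute one experiment preset; returns reports keyed by stage name."""
    if experiment not in ("exp1", "exp2", "exp3", "exp4"):
        raise ValueError(f"unknown experiment {experiment!r}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    artifacts: dict[str, str] = {}

    def log(msg: str) -> None:
        log_lines.append(f"{time.strftime('%Y-%m-%d %H:%M:%S')} {msg}")

    def save_features(fm: FeatureMatrix, name: str) -> None:
        p = out / f"{name}.csv"
        fm.to_csv(p)
        artifacts[p.name] = _sha256(p)

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED ({exc})")
                    (out / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log(f"stage {name}: done")
        return _Stage()

    seeds = {
        "dataset": cfg.seed,
        "split": cfg.seed + 1,
        "augment": cfg.seed + 2,
        "backbone_base": cfg.seed + 10,
        "train_base": cfg.seed + 20,
        "classifier": cfg.seed + 30,
    }
    reports: dict[str, EvaluationReport] = {}

    with stage("prepare"):
        if "root" in cfg.dataset:
            imgset = load_image_dataset(cfg.dataset["root"])
        else:
            synth = dict(cfg.dataset["synthetic"])
            synth.setdefault("seed", seeds["dataset"])
            imgset = generate_texture_dataset(TextureDatasetSpec(**synth))
        train_idx, test_idx = stratified_split(imgset.labels, cfg.split)
        export_split_csv(out / "split.csv", train_idx, test_idx)
        artifacts["split.csv"] = _sha256(out / "split.csv")
        train_set = imgset.subset(train_idx)
        test_set = imgset.subset(test_idx)
        if cfg.augment is not None:
            train_set = augment_training_set(train_set, cfg.augment)
        class_names = imgset.class_names
        n_classes = len(class_names)
        log(f"dataset: {len(imgset)} tiles, {n_classes} classes; "
            f"train {len(train_set)}, test {len(test_set)}")

    kind, clf_spec = _classifier_for(cfg, seeds["classifier"])
    parts_train: list[FeatureMatrix] = []
    parts_test: list[FeatureMatrix] = []
    reduced_train: list[FeatureMatrix] = []
    reduced_test: list[FeatureMatrix] = []

    for i, braw in enumerate(cfg.backbones):
        bdict = {k: v for k, v in braw.items() if k != "finetune"}
        bspec = BackboneSpec(**bdict)
        name = bspec.name
        # disambiguate artifact/report names when an architecture repeats
        tag = name if sum(1 for b in cfg.backbones
                          if (b["name"] if isinstance(b, dict) else b) == name) == 1 \
            else f"{name}_{i}"
        with stage(f"extract[{name}]"):
            if name in CNN_ARCHITECTURES:
                tr = resize_for_backbone(train_set, name)
                te = resize_for_backbone(test_set, name)
            else:
                tr, te = train_set, test_set
            handle = build_backbone(bspec, n_classes,
                                    seed=seeds["backbone_base"] + i)
            if experiment == "exp1" or braw.get("finetune"):
                finetune_backbone(handle, tr, cfg.train,
                                  seed=seeds["train_base"] + i)
            Ftr = extract_features(handle, tr)
            Fte = extract_features(handle, te)
            save_features(Ftr, f"features_{tag}_train")
            save_features(Fte, f"features_{tag}_test")

        if experiment == "exp1":
            with stage(f"evaluate[{name}:head]"):
                scores = handle.head_scores(Fte.values)
                pred = np.argmax(scores, axis=1)
                reports[f"exp1_{tag}"] = evaluate_predictions(
                    Fte.labels, pred, class_names, scores)
            continue

        if experiment == "exp2":
            with stage(f"classify[{name}:raw]"):
                reports[f"exp2_{tag}"] = _fit_eval(kind, clf_spec, Ftr, Fte,
                                                    class_names)
            parts_train.append(Ftr)
            parts_test.append(Fte)
            continue

        with stage(f"reduce[{name}]"):
            if isinstance(cfg.reduce_keep, list):
                keep = int(cfg.reduce_keep[i])
            else:
                keep = int(cfg.reduce_keep.get(
                    name, _default_keep(name, Ftr.n_features)))
            scfg = SpectralConfig(n_coefficients=keep, mode=cfg.spectral_mode)
            Rtr = reduce_features_dct(Ftr, scfg)
            Rte = reduce_features_dct(Fte, scfg)
            save_features(Rtr, f"dct_{tag}_train")
            save_features(Rte, f"dct_{tag}_test")
        if experiment == "exp3":
            with stage(f"classify[{name}:dct]"):
                reports[f"exp3_{tag}"] = _fit_eval(kind, clf_spec, Rtr, Rte,
                                                    class_names)
        parts_train.append(Ftr)
        parts_test.append(Fte)
        reduced_train.append(Rtr)
        reduced_test.append(Rte)

    if experiment == "exp4":
        with stage("fuse"):
            fcfg = SpectralConfig(n_coefficients=cfg.fusion_keep,
                                  mode=cfg.spectral_mode)
            fused_tr = fuse_features_dct(parts_train, fcfg)
            fused_te = fuse_features_dct(parts_test, fcfg)
            save_features(fused_tr, "fused_train")
            save_features(fused_te, "fused_test")
        with stage("classify[fused]"):
            reports["exp4_fused"] = _fit_eval(kind, clf_spec, fused_tr,
                                              fused_te, class_names)
        with stage("select"):
            if cfg.anova_input == "fused":
                Str, Ste = fused_tr, fused_te
            else:
                Str = fuse_concat(reduced_train)
                Ste = fuse_concat(reduced_test)
            scores = anova_f_scores(Str)
            for k in cfg.anova_grid:
                if k > Str.n_features:
                    raise ValueError(
                        f"anova k={k} exceeds {Str.n_features} available features")
                sel = select_top_k(scores, k)
                Ktr = apply_selection(Str, sel)
                Kte = apply_selection(Ste, sel)
                reports[f"exp4_anova_k{k}"] = _fit_eval(kind, clf_spec, Ktr,
                                                        Kte, class_names)

    with stage("report"):
        for rname, rep in reports.items():
            rep.to_json(out / f"report_{rname}.json")
            rep.confusion.to_csv(out / f"confusion_{rname}.csv")
            artifacts[f"report_{rname}.json"] = _sha256(out / f"report_{rname}.json")
        manifest = {
            "package_version": __version__,
            "experiment": experiment,
            "config": cfg.to_dict(),
            "seeds": seeds,
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return reports


def fuse_concat(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Plain column-wise concatenation of aligned feature matrices."""
    if not parts:
        raise ValueError("no feature matrices to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if not np.array_equal(p.labels, first.labels):
            raise ValueError("parts must share labels and ordering")
    return FeatureMatrix(
        np.hstack([p.values for p in parts]), first.labels.copy(),
        feature_origin="concat", class_names=first.class_names,
        meta={"part_order": [p.feature_origin for p in parts]},
    )


def desk_config(seed: int = 0, output_dir: str | Path = "histospect_run",
                classifier_kind: str = "cubic_svm") -> PipelineConfig:
    """Desk-scale preset: synthetic 4-class grating tiles, spectral
    pseudo-backbones at three resolutions, 70-30 split, fusion at ~50% of
    the concatenated width, ANOVA top-200 and a cubic SVM."""
    raw = {
        "dataset": {"synthetic": {"n_classes": 4, "per_class": 60,
                                  "tile_size": 150, "noise_sd": 0.05,
                                  "seed": seed}},
        "split": {"train_fraction": 0.70, "seed": seed + 1},
        "backbones": [
            {"name": "dct_energy", "expected_dim": 1024},
            {"name": "dct_energy", "expected_dim": 576},
            {"name": "dct_energy", "expected_dim": 256},
        ],
        "reduce": {"keep": [512, 288, 128]},
        "fusion": {"n_coefficients": (1024 + 576 + 256) // 2},
        "anova": {"k": 200, "input": "fused"},
        "classifier": {"kind": classifier_kind},
        "output_dir": str(output_dir),
        "seed": seed,
    }
    return config_from_dict(raw)
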
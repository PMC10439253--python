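"""End-to-end orchestration: simulate -> preprocess -> extract -> train ->
predict -> evaluate, with seed control and a provenance manifest.

Cohort splits mirror a training/validation cohort design: either fractions
(resolved to deterministic case-id lists under the run seed) or explicit
case-id lists. Standardization statistics and the operating threshold are
always derived on the training split only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvalReport, evaluate_scores, youden_cutoff
from .exceptions import ConfigError, DataError, LeakageError, VersionMismatchError
from .features import (
    FEATURE_DICT_VERSION,
    RadiomicsVector,
    StandardizationStats,
    extract_radiomics,
    feature_names,
    zscore_apply,
    zscore_fit,
)
from .nn.model import (
    BackboneConfig,
    FusionHeadConfig,
    HRRadNet,
    build_model,
    load_checkpoint,
    paper_like_preset,
    save_checkpoint,
    tiny_preset,
)
from .phantoms import PhantomCase, PhantomSpec, generate_cases, generate_cohort
from .training import Dataset, FocalLossParams, TrainConfig, TrainHistory, train
from .volumes import (
    CTVolume,
    ModelInput,
    ROIMask,
    WindowSpec,
    build_input,
    read_case,
    resample_mask,
    resample_volume,
    window_normalize,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (0.75, 0.75, 2.5)
    window: tuple[float, float] = (-150.0, 150.0)
    size: int = 64
    margin: float = 0.25


@dataclass(frozen=True)
class SplitSpec:
    """Either fractions (summing to 1) or explicit case-id lists."""

    fractions: dict[str, float] | None = None
    case_lists: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if (self.fractions is None) == (self.case_lists is None):
            raise ConfigError("provide exactly one of fractions or case_lists")
        if self.fractions is not None:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"split fractions must sum to 1, got {total}")
        if self.case_lists is not None:
            seen: set[str] = set()
            for name, ids in self.case_lists.items():
                overlap = seen & set(ids)
                if overlap:
                    raise LeakageError(
                        f"case ids appear in multiple splits: {sorted(overlap)[:5]}"
                    )
                seen |= set(ids)


@dataclass
class RunConfig:
    seed: int = 0
    n_cases: int = 200
    phantoms: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bins: tuple[int, ...] = (8, 16, 32, 64)
    split: SplitSpec = field(default_factory=lambda: SplitSpec(fractions={"train": 0.7, "val": 0.3}))
    preset: str = "tiny"
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: FocalLossParams = field(default_factory=FocalLossParams)
    out_dir: str = "dlrs_run"
    write_volumes: bool = False  # keep NIfTI round-trip optional for speed


# ----------------------------------------------------------------- preprocessing


def preprocess_case(vol: CTVolume, mask: ROIMask, cfg: PreprocessConfig,
                    case_id: str = "") -> tuple[ModelInput, RadiomicsVector]:
    """Resample, window, and produce both the network input and radiomics vector."""
    vol_r = resample_volume(vol, cfg.target_spacing)
    mask_r = resample_mask(mask, cfg.target_spacing)
    w = WindowSpec(*cfg.window)
    inp = build_input(vol_r, mask_r, w, size=cfg.size, margin=cfg.margin, case_id=case_id)
    vol_n = window_normalize(vol_r, w)
    vec = extract_radiomics(vol_n, mask_r, case_id=case_id)
    return inp, vec


def preprocess_cohort(cases: list[PhantomCase], cfg: PreprocessConfig):
    """Arrays for a list of in-memory cases: images, raw radiomics, labels, ids."""
    inputs, vectors, labels, ids = [], [], [], []
    for case in cases:
        inp, vec = preprocess_case(case.volume, case.mask, cfg, case_id=case.case_id)
        inputs.append(inp.channels)
        vectors.append(vec)
        labels.append(case.label)
        ids.append(case.case_id)
    return np.stack(inputs), vectors, np.asarray(labels, dtype=int), ids


def features_to_frame(vectors: list[RadiomicsVector]) -> pd.DataFrame:
    """Feature table: rows = cases, first column case_id, then the 361 features."""
    df = pd.DataFrame([v.values for v in vectors], columns=vectors[0].names)
    df.insert(0, "case_id", [v.case_id for v in vectors])
    return df


# ------------------------------------------------------------------- splitting


def resolve_split(case_ids: list[str], split: SplitSpec, seed: int) -> dict[str, list[str]]:
    """Deterministic split resolution; validates coverage and non-overlap."""
    if split.case_lists is not None:
        known = set(case_ids)
        for name, ids in split.case_lists.items():
            unknown = set(ids) - known
            if unknown:
                raise DataError(f"split {name!r} references unknown cases {sorted(unknown)[:5]}")
        return {k: list(v) for k, v in split.case_lists.items()}
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(case_ids))
    out: dict[str, list[str]] = {}
    start = 0
    names = list(split.fractions)
    for i, name in enumerate(names):
        stop = len(order) if i == len(names) - 1 else start + round(split.fractions[name] * len(order))
        out[name] = order[start:stop]
        start = stop
    return out


def make_datasets(images: np.ndarray, vectors: list[RadiomicsVector],
                  labels: np.ndarray, ids: list[str],
                  split_ids: dict[str, list[str]]):
    """Standardize on the training split and assemble Dataset objects."""
    index = {cid: i for i, cid in enumerate(ids)}
    train_idx = [index[c] for c in split_ids["train"]]
    stats = zscore_fit([vectors[i] for i in train_idx])
    Z = np.stack([zscore_apply(v, stats).values for v in vectors])
    datasets = {}
    for name, id_list in split_ids.items():
        idx = [index[c] for c in id_list]
        datasets[name] = Dataset(
            images=images[idx], radiomics=Z[idx], labels=labels[idx],
            case_ids=list(id_list),
        )
    return datasets, stats


# -------------------------------------------------------------------- pipeline


def _preset(name: str) -> tuple[BackboneConfig, FusionHeadConfig]:
    if name == "tiny":
        return tiny_preset()
    if name == "paper_like":
        return paper_like_preset()
    raise ConfigError(f"unknown preset {name!r}")


def _sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = dataclasses.replace(config.phantoms, seed=config.seed)
    if config.write_volumes:
        generate_cohort(spec, config.n_cases, out / "cohort")
    cases = generate_cases(spec, config.n_cases)

    images, vectors, labels, ids = preprocess_cohort(cases, config.preprocess)
    features_to_frame(vectors).to_csv(out / "features.csv", index=False)

    split_ids = resolve_split(ids, config.split, config.seed)
    if "train" not in split_ids or "val" not in split_ids:
        raise ConfigError("split must define 'train' and 'val'")
    datasets, stats = make_datasets(images, vectors, labels, ids, split_ids)

    backbone, head = _preset(config.preset)
    model = build_model(backbone, head, seed=config.seed)
    train_cfg = dataclasses.replace(config.train, seed=config.seed)
    model, history = train(model, datasets["train"], datasets["val"], train_cfg, config.loss)

    ckpt_path = out / "checkpoint.npz"
    save_checkpoint(ckpt_path, model, standardization=stats,
                    feature_dict_version=FEATURE_DICT_VERSION,
                    extra={"preset": config.preset, "seed": config.seed})

    train_scores = model.predict_proba(datasets["train"].images, datasets["train"].radiomics)
    val_scores = model.predict_proba(datasets["val"].images, datasets["val"].radiomics)
    cutoff = youden_cutoff(train_scores, datasets["train"].labels)
    report = evaluate_scores(val_scores, datasets["val"].labels,
                             threshold=cutoff.threshold, seed=config.seed)

    pd.DataFrame({"case_id": datasets["val"].case_ids, "dlrs": val_scores,
                  "label": datasets["val"].labels}).to_csv(out / "scores_val.csv", index=False)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_cases": config.n_cases,
        "feature_dict_version": FEATURE_DICT_VERSION,
        "split_sizes": {k: len(v) for k, v in split_ids.items()},
        "checkpoint": str(ckpt_path),
        "checkpoint_hash": _sha256_file(ckpt_path),
        "history": {"losses": history.losses, "lrs": history.lrs,
                    "val_aucs": history.val_aucs, "best_epoch": history.best_epoch},
        "train_cutoff": asdict(cutoff),
        "eval_report": report.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def phantom_experiment(seed: int, n_cases: int = 400, n_epochs: int = 12,
                       spec: PhantomSpec | None = None, ablation: str | None = None,
                       preset: str = "tiny") -> dict:
    """One planted-signal recovery experiment: generate, preprocess, train, score.

    Uses a train/val/test split (60/15/25): the checkpoint is selected on the
    validation split and the reported AUC is measured on the untouched test
    split, so checkpoint selection cannot inflate the reported performance
    (this matters for null-configuration cohorts, where picking the best of
    several noisy validation AUCs would bias the estimate above 0.5).
    ``ablation`` may be 'no_radiomics' or 'no_se' to train a variant model on
    the same cohort and split.
    """
    from .evaluation import roc_auc
    from .nn.model import ablate as ablate_model

    spec = dataclasses.replace(spec or PhantomSpec(), seed=seed)
    cases = generate_cases(spec, n_cases)
    images, vectors, labels, ids = preprocess_cohort(cases, PreprocessConfig())
    split_ids = resolve_split(
        ids, SplitSpec(fractions={"train": 0.6, "val": 0.15, "test": 0.25}), seed
    )
    datasets, _ = make_datasets(images, vectors, labels, ids, split_ids)
    backbone, head = _preset(preset)
    model = build_model(backbone, head, seed=seed)
    if ablation is not None:
        model = ablate_model(model, ablation)
    model, history = train(
        model, datasets["train"], datasets["val"],
        TrainConfig(n_epochs=n_epochs, seed=seed),
    )
    test = datasets["test"]
    scores = model.predict_proba(test.images, test.radiomics)
    return {
        "auc": roc_auc(scores, test.labels) if len(np.unique(test.labels)) > 1 else float("nan"),
        "scores": scores,
        "labels": test.labels,
        "history": history,
        "n_train": len(datasets["train"]),
        "n_test": len(test),
    }


def predict(ckpt_path, images: np.ndarray, vectors: list[RadiomicsVector]) -> pd.DataFrame:
    """Score cases with a checkpoint; refuses on feature-schema version mismatch."""
    model, stats, meta = load_checkpoint(
        ckpt_path, expected_feature_dict_version=FEATURE_DICT_VERSION
    )
    if stats is None:
        raise VersionMismatchError("checkpoint lacks standardization statistics")
    Z = np.stack([zscore_apply(v, stats).values for v in vectors])
    scores = model.predict_proba(images, Z)
    return pd.DataFrame({"case_id": [v.case_id for v in vectors], "dlrs": scores})
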
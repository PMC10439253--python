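"""The DLRS fusion network.

A multi-resolution convolutional backbone (HR-Net-style parallel streams: the
high-resolution stream is kept throughout while lower-resolution,
double-width streams are added and exchanged with it each stage), a
squeeze-and-excitation gate at the end of every branch, a fully connected
embedding of the 361 standardized radiomics features, and a fused fully
connected head emitting one probability (the deep-learning radiomics score,
DLRS) that the tumor is TME-high.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..exceptions import ConfigError, DataError, VersionMismatchError
from .autodiff import Tensor, concat, upsample_nearest
from .layers import Conv2d, Linear, Module, SEBlock, global_avg_pool


@dataclass(frozen=True)
class SEConfig:
    """Squeeze-and-excitation reduction ratio (hidden width = C / r, clamped to >= 1)."""

    reduction_ratio: int = 16

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ConfigError("reduction_ratio must be >= 1")


@dataclass(frozen=True)
class BackboneConfig:
    """Backbone scale: resolution streams double in width as resolution halves."""

    n_stages: int = 2
    base_width: int = 8
    branches_per_stage: int = 2
    se: SEConfig = field(default_factory=SEConfig)

    def __post_init__(self) -> None:
        if self.n_stages < 2 or self.base_width < 1 or self.branches_per_stage < 1:
            raise ConfigError(f"invalid backbone config {self}")


@dataclass(frozen=True)
class FusionHeadConfig:
    radiomics_dim: int = 361
    embed_dim: int = 64
    hidden_dim: int = 128

    def __post_init__(self) -> None:
        if min(self.radiomics_dim, self.embed_dim, self.hidden_dim) < 1:
            raise ConfigError(f"invalid head config {self}")


def tiny_preset() -> tuple[BackboneConfig, FusionHeadConfig]:
    """CPU-scale preset used by the test and phantom studies."""
    return (
        BackboneConfig(n_stages=2, base_width=8, branches_per_stage=2, se=SEConfig(4)),
        FusionHeadConfig(embed_dim=32, hidden_dim=64),
    )


def paper_like_preset() -> tuple[BackboneConfig, FusionHeadConfig]:
    """A fuller-scale configuration for real training runs."""
    return (
        BackboneConfig(n_stages=4, base_width=18, branches_per_stage=3, se=SEConfig(16)),
        FusionHeadConfig(embed_dim=64, hidden_dim=128),
    )


class _Stage(Module):
    """One stage: per-branch conv + ReLU + SE, then cross-resolution exchange."""

    def __init__(self, widths: list[int], se_cfg: SEConfig, rng: np.random.Generator):
        self.widths = list(widths)
        self.convs = [Conv2d(w, w, rng) for w in widths]
        self.se_blocks = [SEBlock(w, se_cfg.reduction_ratio, rng) for w in widths]
        # fuse[j][i]: transform branch i's map to branch j's resolution/width
        self.fuse: list[list[Module | None]] = []
        for j, wj in enumerate(widths):
            row: list[Module | None] = []
            for i, wi in enumerate(widths):
                if i == j:
                    row.append(None)
                elif i < j:  # downsample: one strided 3x3 conv per halving
                    row.append(_DownPath(wi, wj, j - i, rng))
                else:  # upsample: 1x1 conv then nearest upsample
                    row.append(_UpPath(wi, wj, i - j, rng))
            self.fuse.append(row)

    def __call__(self, branches: list[Tensor]) -> list[Tensor]:
        feats = [
            se(conv(x).relu())
            for x, conv, se in zip(branches, self.convs, self.se_blocks)
        ]
        fused = []
        for j in range(len(feats)):
            acc = feats[j]
            for i in range(len(feats)):
                if i != j:
                    acc = acc + self.fuse[j][i](feats[i])
            fused.append(acc.relu())
        return fused


class _DownPath(Module):
    def __init__(self, in_w: int, out_w: int, n_halvings: int, rng):
        self.convs = []
        w = in_w
        for k in range(n_halvings):
            nxt = out_w if k == n_halvings - 1 else w * 2
            self.convs.append(Conv2d(w, nxt, rng, stride=2))
            w = nxt

    def __call__(self, x: Tensor) -> Tensor:
        for i, c in enumerate(self.convs):
            x = c(x)
            if i < len(self.convs) - 1:
                x = x.relu()
        return x


class _UpPath(Module):
    def __init__(self, in_w: int, out_w: int, n_doublings: int, rng):
        self.scale = 2**n_doublings
        self.conv = Conv2d(in_w, out_w, rng, k=1, pad=0)

    def __call__(self, x: Tensor) -> Tensor:
        return upsample_nearest(self.conv(x), self.scale)


class HRRadNet(Module):
    """Fusion network: image branches + radiomics embedding -> one probability."""

    def __init__(self, backbone: BackboneConfig, head: FusionHeadConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.backbone_cfg = backbone
        self.head_cfg = head
        self.use_radiomics = True
        w = backbone.base_width

        # two stride-2 stem convolutions: branch 0 runs at 1/4 input resolution
        self.stem1 = Conv2d(3, w, rng, stride=2)
        self.stem2 = Conv2d(w, w, rng, stride=2)

        widths = [w]
        self.transitions: list[Conv2d] = []
        self.stages: list[_Stage] = []
        for _ in range(backbone.n_stages):
            if len(widths) < backbone.branches_per_stage:
                self.transitions.append(Conv2d(widths[-1], widths[-1] * 2, rng, stride=2))
                widths = widths + [widths[-1] * 2]
            else:
                self.transitions.append(None)  # type: ignore[arg-type]
            self.stages.append(_Stage(widths, backbone.se, rng))

        img_dim = sum(widths)
        self.rad_embed = Linear(head.radiomics_dim, head.embed_dim, rng)
        self.fc_hidden = Linear(img_dim + head.embed_dim, head.hidden_dim, rng)
        self.fc_out = Linear(head.hidden_dim, 1, rng)
        self.activations: dict[str, Tensor] = {}

    # ------------------------------------------------------------------ forward

    def forward(self, images: Tensor, radiomics: Tensor, capture: bool = False) -> Tensor:
        """Probability per case. ``images`` (B,3,S,S); ``radiomics`` (B, radiomics_dim)."""
        if radiomics.data.ndim != 2 or radiomics.data.shape[1] != self.head_cfg.radiomics_dim:
            raise DataError(
                f"radiomics vector length {radiomics.data.shape} != "
                f"expected (*, {self.head_cfg.radiomics_dim})"
            )
        self.activations = {}
        x = self.stem2(self.stem1(images).relu()).relu()
        branches = [x]
        for s, (trans, stage) in enumerate(zip(self.transitions, self.stages)):
            if trans is not None:
                branches = branches + [trans(branches[-1]).relu()]
            branches = stage(branches)
            if capture:
                for b, t in enumerate(branches):
                    self.activations[f"stage{s}_branch{b}"] = t
        img_emb = concat([global_avg_pool(b) for b in branches], axis=1)

        rad = self.rad_embed(radiomics).relu()
        if not self.use_radiomics:
            rad = rad * 0.0
        fused = concat([img_emb, rad], axis=1)
        logit = self.fc_out(self.fc_hidden(fused).relu())
        if capture:
            self.activations["logit"] = logit
        return logit.sigmoid().reshape(-1)

    def predict_proba(self, images: np.ndarray, radiomics: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Inference on numpy arrays, batched, deterministic."""
        out = []
        for i in range(0, len(images), batch_size):
            out.append(
                self.forward(
                    Tensor(images[i : i + batch_size]),
                    Tensor(radiomics[i : i + batch_size]),
                ).data
            )
        return np.concatenate(out) if out else np.zeros(0)

    def default_cam_layer(self) -> str:
        """Last highest-resolution branch activation."""
        return f"stage{self.backbone_cfg.n_stages - 1}_branch0"


def build_model(backbone: BackboneConfig | None = None,
                head: FusionHeadConfig | None = None,
                seed: int = 0) -> HRRadNet:
    """Deterministically initialized model; same seed gives bitwise-equal weights."""
    if backbone is None or head is None:
        tb, th = tiny_preset()
        backbone = backbone or tb
        head = head or th
    return HRRadNet(backbone, head, seed)


def ablate(model: HRRadNet, mode: str) -> HRRadNet:
    """Ablation variants: 'no_radiomics' drops the radiomics branch,
    'no_se' fixes every SE gate at identity."""
    if mode not in ("no_radiomics", "no_se"):
        raise ConfigError(f"unknown ablation mode {mode!r}")
    variant = copy.deepcopy(model)
    if mode == "no_radiomics":
        variant.use_radiomics = False
    else:
        for stage in variant.stages:
            for se in stage.se_blocks:
                se.identity = True
    return variant


# ------------------------------------------------------------------ checkpoints


def save_checkpoint(path, model: HRRadNet, *, standardization=None,
                    feature_dict_version: str = "", extra: dict | None = None) -> None:
    """Single-archive checkpoint: weights + config + schema version + z-score stats."""
    meta = {
        "backbone": asdict(model.backbone_cfg),
        "head": asdict(model.head_cfg),
        "use_radiomics": model.use_radiomics,
        "feature_dict_version": feature_dict_version,
        "extra": extra or {},
    }
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    if standardization is not None:
        arrays["zscore::mean"] = standardization.mean
        arrays["zscore::std"] = standardization.std
        meta["zscore_names"] = standardization.names
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, expected_feature_dict_version: str | None = None):
    """Rebuild (model, standardization_stats, meta) from a checkpoint archive."""
    from ..features.bank import StandardizationStats

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if (
            expected_feature_dict_version is not None
            and meta["feature_dict_version"] != expected_feature_dict_version
        ):
            raise VersionMismatchError(
                f"checkpoint feature dictionary {meta['feature_dict_version']!r} != "
                f"expected {expected_feature_dict_version!r}"
            )
        backbone = BackboneConfig(
            n_stages=meta["backbone"]["n_stages"],
            base_width=meta["backbone"]["base_width"],
            branches_per_stage=meta["backbone"]["branches_per_stage"],
            se=SEConfig(**meta["backbone"]["se"]),
        )
        head = FusionHeadConfig(**meta["head"])
        model = HRRadNet(backbone, head, seed=0)
        model.use_radiomics = meta["use_radiomics"]
        state = {
            k.removeprefix("param::"): data[k] for k in data.files if k.startswith("param::")
        }
        model.load_state_dict(state)
        stats = None
        if "zscore::mean" in data.files:
            stats = StandardizationStats(
                mean=data["zscore::mean"], std=data["zscore::std"],
                names=list(meta["zscore_names"]),
            )
    return model, stats, meta
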
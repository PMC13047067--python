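"""Run configuration: one flat, YAML-serializable record of every knob.

Defaults equal the reference configuration where one is stated (300 epochs,
lr 1e-3, hidden 256, embedding 128, fusion weights 0.6/0.3/0.1, loss
0.7·BCE + 0.3·Focal with alpha 0.25 and gamma 2, ontology decay 0.5).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .metapath import FusionWeights
from .training import LossConfig, TrainConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input paths
    m1a_circ: str = "m1a_circ.tsv"
    circ_disease: str = "circ_disease.tsv"
    m1a_disease: str = "m1a_disease.tsv"
    windows: str = "windows.fasta"
    ontology: str = "ontology.obo"
    outdir: str = "out"
    seed: int = 0
    # similarity
    ontology_decay: float = 0.5
    # meta-path fusion
    weights_m: list = field(default_factory=lambda: [0.6, 0.3, 0.1])
    weights_d: list = field(default_factory=lambda: [0.6, 0.3, 0.1])
    # model
    model_layers: int = 3
    model_hidden: int = 256
    model_embed: int = 128
    model_heads: int = 4
    model_mlp: list = field(default_factory=lambda: [32, 64, 32])
    # training
    train_epochs: int = 300
    train_lr: float = 1e-3
    train_threshold: float = 0.5
    train_folds: int = 5
    leaky_similarity: bool = False
    # loss
    loss_bce_weight: float = 0.7
    loss_focal_weight: float = 0.3
    loss_alpha: float = 0.25
    loss_gamma: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def apply_overrides(self, overrides) -> "RunConfig":
        """Apply ``key=value`` strings; values are parsed as YAML scalars."""
        data = asdict(self)
        for item in overrides:
            key, sep, value = item.partition("=")
            if not sep:
                raise ValueError(f"override {item!r} is not of the form key=value")
            if key not in data:
                raise ValueError(f"unknown config key: {key!r}")
            data[key] = yaml.safe_load(value)
        return RunConfig(**data)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            n_folds=self.train_folds, epochs=self.train_epochs, lr=self.train_lr,
            threshold=self.train_threshold,
            weights_m=FusionWeights(*self.weights_m),
            weights_d=FusionWeights(*self.weights_d),
            loss=LossConfig(bce_weight=self.loss_bce_weight,
                            focal_weight=self.loss_focal_weight,
                            focal_alpha=self.loss_alpha,
                            focal_gamma=self.loss_gamma),
            leaky_similarity=self.leaky_similarity,
            n_layers=self.model_layers, hidden_dim=self.model_hidden,
            embed_dim=self.model_embed, n_heads=self.model_heads,
            mlp_hidden=tuple(self.model_mlp))

    def digest(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]
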
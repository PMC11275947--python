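"""Run configuration: every tunable of the pipeline with its default.

Defaults reproduce the selected operating point: TSS range 200 bp, learning
rate 0.01, hidden size 128, 100 training epochs, with 10 bp bins, average
graph degree 10, 5 expression classes for the view-level classifiers, and a
70/15/15 random split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    tss_range: int = 200          # bp flank per side of the TSS
    bin_size: int = 10            # bp per feature bin
    avg_degree: float = 10        # target mean degree of the sample graph
    n_classes: int = 5            # expression quantile bins for the view GCNs
    hidden_size: int = 128        # GCN hidden units; also the fusion hidden size
    lr: float = 0.01
    epochs: int = 100             # stage-2 (fusion) training epochs
    pretrain_epochs: int = 50     # stage-1 per-view pretraining epochs
    dropout: float = 0.5
    weight_decay: float = 5e-4
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    patience: int = 20            # early stopping on validation MSE
    min_epochs: int = 60          # burn-in before early stopping may fire
    fusion_steps: int = 20        # regression updates per alternation round
    label_smoothing: float = 0.3  # softens view-classifier targets
    similarity_sharpening: float = 32  # exponent on cosine edge weights
    seed: int = 0

    @property
    def fusion_hidden(self) -> int:
        return self.hidden_size

    def __post_init__(self) -> None:
        if self.tss_range <= 0 or self.bin_size <= 0:
            raise ValueError("tss_range and bin_size must be positive")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lr < 0 or self.weight_decay < 0:
            raise ValueError("lr and weight_decay must be non-negative")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.similarity_sharpening < 1 or self.fusion_steps < 1:
            raise ValueError("similarity_sharpening and fusion_steps must be >= 1")
        fr = tuple(self.fractions)
        if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or min(fr) <= 0:
            raise ValueError("fractions must be 3 positive values summing to 1")
        self.fractions = fr

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        if "fractions" in d:
            d = {**d, "fractions": tuple(d["fractions"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
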
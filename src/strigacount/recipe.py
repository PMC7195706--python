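"""Training-recipe metadata: the detector's training hyperparameters as config.

The detector itself is trained elsewhere; this module only records and
round-trips the recipe (optimizer settings, schedule, input resolution,
augmentation flags, anchor set) as a YAML document, so a run's provenance is
reproducible.  Defaults are the standard recipe for this assay: SGD with
momentum 0.9, learning rate 1e-3, weight decay 5e-4, 20 000 epochs with the
learning rate divided by 10 at epochs 16 000 and 18 000, 608 px input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .anchors import AnchorSet


@dataclass(frozen=True)
class TrainingRecipe:
    optimizer: str = "sgd"
    momentum: float = 0.9
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 20000
    lr_drop_epochs: tuple[int, ...] = (16000, 18000)
    lr_drop_factor: float = 10.0
    input_resolution: int = 608
    augmentation: dict[str, bool] = field(
        default_factory=lambda: {
            "hsv_shift": True,
            "horizontal_flip": True,
            "jitter": True,
        }
    )
    anchors: AnchorSet | None = None

    def __post_init__(self) -> None:
        for name in ("momentum", "learning_rate", "weight_decay", "lr_drop_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs <= 0 or self.input_resolution <= 0:
            raise ValueError("max_epochs and input_resolution must be positive")
        object.__setattr__(self, "lr_drop_epochs", tuple(self.lr_drop_epochs))
        if any(e >= self.max_epochs for e in self.lr_drop_epochs):
            raise ValueError("lr_drop_epochs must be below max_epochs")


def write_training_recipe(recipe: TrainingRecipe, path=None) -> str:
    """Serialize a recipe to YAML; optionally also write it to ``path``."""
    data = asdict(recipe)
    data["lr_drop_epochs"] = list(recipe.lr_drop_epochs)
    if recipe.anchors is not None:
        data["anchors"] = [list(s) for s in recipe.anchors]
    doc = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(doc)
    return doc


def read_training_recipe(source) -> TrainingRecipe:
    """Parse a YAML recipe document (string, path, or mapping)."""
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists())
            else str(source)
        )
        data = yaml.safe_load(text)
    anchors = data.get("anchors")
    if anchors is not None:
        data["anchors"] = AnchorSet(tuple((w, h) for w, h in anchors))
    data["lr_drop_epochs"] = tuple(data.get("lr_drop_epochs", ()))
    return TrainingRecipe(**data)
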
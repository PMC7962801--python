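"""Run configuration with the experiment's stated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .records import DEFAULT_STYLES, StyleSet


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field lands in the manifest.

    Defaults follow the experiments analyzed here: a 1280×1024 screen with a
    centered 824 px square image, a 10×10 analysis grid, 150 ms fast-guess
    threshold, ±3.5 SD winsorization, and the eight-style roster.
    """

    styles: tuple[str, ...] = DEFAULT_STYLES
    screen_width: int = 1280
    screen_height: int = 1024
    image_size: int = 824
    grid_size: int = 10
    fast_guess_threshold_s: float = 0.150
    winsorize_k: float = 3.5
    rt_correct_only: bool = False
    correlation_to_distance: str = "one_minus_r"
    weighted_linkage: bool = False
    asymmetry_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.styles = tuple(self.styles)
        StyleSet(self.styles)  # validates
        if self.image_size > min(self.screen_width, self.screen_height):
            raise ValueError("image must fit on the screen")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.fast_guess_threshold_s <= 0 or self.winsorize_k <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def style_set(self) -> StyleSet:
        return StyleSet(self.styles)

    @property
    def screen_size(self) -> tuple[int, int]:
        return (self.screen_width, self.screen_height)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["styles"] = list(self.styles)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
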
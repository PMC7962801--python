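"""Core record types shared by the search and gaze pipelines.

Coordinates are screen pixels, origin top-left, x rightward, y downward,
0-based. Reaction times are seconds. Target/response locations are quadrant
codes (one of :data:`LOCATIONS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

#: Quadrant codes for the 2x2 singleton-search layout.
LOCATIONS: tuple[str, ...] = ("TL", "TR", "BL", "BR")

#: Default roster of eight styles: early/late Impressionism, early/late
#: Expressionism, Gauguin, Photography, Cézanne, van Gogh.
DEFAULT_STYLES: tuple[str, ...] = ("EI", "LI", "EE", "LE", "G", "P", "C", "VG")


@dataclass(frozen=True)
class StyleSet:
    """Ordered roster of style labels; the order fixes all matrix indexing."""

    labels: tuple[str, ...] = DEFAULT_STYLES

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a style roster needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate style labels in roster: {labels}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown style label {label!r}; roster is {self.labels}") from None

    def ordered_pairs(self) -> list[tuple[str, str]]:
        """All ordered (target, distractor) pairs, target != distractor."""
        return [(t, d) for t in self.labels for d in self.labels if t != d]


@dataclass(frozen=True)
class TrialSkeleton:
    """One planned singleton-search trial before behavior is simulated."""

    block: int
    target_style: str
    distractor_style: str
    motif: str
    target_location: str

    def __post_init__(self) -> None:
        if self.target_style == self.distractor_style:
            raise ValueError("target and distractor style must differ")
        if self.target_location not in LOCATIONS:
            raise ValueError(f"target_location must be one of {LOCATIONS}")


@dataclass(frozen=True)
class TrialRecord:
    """One completed singleton-search trial.

    Correctness is derived, never stored: a trial is correct iff
    ``response_location == target_location``.
    """

    subject: str
    block: int
    target_style: str
    distractor_style: str
    target_location: str
    response_location: str
    rt: float

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"rt must be positive, got {self.rt}")
        if self.target_style == self.distractor_style:
            raise ValueError("target and distractor style must differ")
        for loc in (self.target_location, self.response_location):
            if loc not in LOCATIONS:
                raise ValueError(f"location {loc!r} not one of {LOCATIONS}")

    @property
    def correct(self) -> bool:
        return self.response_location == self.target_location

    def with_rt(self, rt: float) -> "TrialRecord":
        return TrialRecord(
            subject=self.subject,
            block=self.block,
            target_style=self.target_style,
            distractor_style=self.distractor_style,
            target_location=self.target_location,
            response_location=self.response_location,
            rt=rt,
        )


@dataclass(frozen=True)
class Viewing:
    """One planned free-viewing presentation: a subject sees one motif in one style."""

    subject: str
    block: int
    motif: str
    style: str


@dataclass(frozen=True)
class FixationRecord:
    """One fixation on a stimulus, in screen-pixel coordinates."""

    subject: str
    motif: str
    style: str
    x: float
    y: float
    duration_ms: Optional[float] = None


def validate_styles(labels: Iterable[str], styles: StyleSet) -> None:
    """Raise KeyError if any label is outside the roster."""
    unknown = sorted(set(labels) - set(styles.labels))
    if unknown:
        raise KeyError(f"unknown style label(s) {unknown}; roster is {styles.labels}")
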
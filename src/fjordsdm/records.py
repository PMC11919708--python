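"""Point and effort record containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SightingSet:
    """Presence points for one month, planar coordinates in metres."""

    month_id: str
    points: np.ndarray  # (n, 2) array of (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month_id": self.month_id, "x": self.points[:, 0], "y": self.points[:, 1]}
        )


@dataclass
class PseudoAbsenceSet:
    """Effort-proportional background points for one month."""

    month_id: str
    points: np.ndarray  # (n, 2)
    generator_seed: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month_id": self.month_id,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "seed": self.generator_seed,
            }
        )


@dataclass
class EffortRecord:
    """Monthly survey effort: total hours searched and days with >= 1 tour."""

    month_id: str
    effort_hours: float
    search_days: int

    def __post_init__(self) -> None:
        if self.effort_hours < 0 or self.search_days < 0:
            raise ValueError("effort_hours and search_days must be nonnegative")
        if self.search_days == 0 and self.effort_hours > 0:
            raise ValueError("effort hours without search days is inconsistent")


@dataclass
class Trackline:
    """One boat tour's GPS path, ordered planar vertices."""

    vertices: np.ndarray  # (k, 2), k >= 2
    month_id: str
    day: int = field(default=1)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("a trackline needs at least 2 vertices")

    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))
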
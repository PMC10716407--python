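"""Shared domain types for in-situ-microscopy population monitoring.

The package follows the six-class morphological catalogue used for
hybridoma cultures imaged by in situ microscopy (ISM): viable single
cells, apoptotic cells, necrotic cells, viable cells displaying surface
bulges, late-stage necrotic cells and pairs of viable cells (mitotic
twins).  Densities are always cell/mL, times in hours, frames 8-bit
grayscale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CellClass",
    "CLASS_COLUMNS",
    "COLUMN_CLASS_IDS",
    "CLASS_ID_TO_COLUMN",
    "VIABLE_COLUMNS",
    "DEAD_COLUMNS",
    "BoundingBox",
    "ProcessEvent",
    "EVENT_KINDS",
    "ClassCountSeries",
]


class CellClass(enum.IntEnum):
    """Morphological cell classes, numbered as in the annotation format."""

    VIABLE = 1            # pseudo-circular, homogeneous texture
    APOPTOTIC = 2         # irregular, shrunken, inhomogeneous, optional vesicles
    NECROTIC = 3          # swollen, almost perfectly round, inhomogeneous
    VIABLE_BULGES = 4     # viable with distinct surface bulges (feast/famine)
    NECROTIC_LATE = 5     # round, inhomogeneous, ruptured (discontinuous) border
    PAIR = 6              # two attached viable cells (mitotic twins)


#: Canonical column order used by every per-class array / CSV in the package.
CLASS_COLUMNS: tuple[str, ...] = (
    "viable",
    "viable_bulges",
    "pair",
    "apoptotic",
    "necrotic",
    "necrotic_late",
)

#: CellClass id of each canonical column.
COLUMN_CLASS_IDS: tuple[int, ...] = (1, 4, 6, 2, 3, 5)

CLASS_ID_TO_COLUMN: dict[int, int] = {c: i for i, c in enumerate(COLUMN_CLASS_IDS)}

#: Column indices pooled into the viable / dead totals.
VIABLE_COLUMNS: tuple[int, ...] = (0, 1, 2)   # viable, viable_bulges, pair
DEAD_COLUMNS: tuple[int, ...] = (3, 4, 5)     # apoptotic, necrotic, necrotic_late


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, normalized to [0, 1], origin at the top-left corner.

    ``cx``/``cy`` are the box centre, ``w``/``h`` its full width/height —
    the convention of darknet/YOLO annotation files.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box centre ({self.cx}, {self.cy}) outside [0, 1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0, 1]")

    def corners(self) -> tuple[float, float, float, float]:
        """Return (x1, y1, x2, y2) corner coordinates."""
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union with another normalized box."""
        ax1, ay1, ax2, ay2 = self.corners()
        bx1, by1, bx2, by2 = other.corners()
        iw = min(ax2, bx2) - max(ax1, bx1)
        ih = min(ay2, by2) - max(ay1, by1)
        if iw <= 0.0 or ih <= 0.0:
            return 0.0
        inter = iw * ih
        union = self.w * self.h + other.w * other.h - inter
        return inter / union


EVENT_KINDS = (
    "gas_blocking",
    "medium_addition",
    "substrate_limitation",
    "oxygen_depletion",
    "oxygen_resupply",
    "feed_start",
)


@dataclass(frozen=True)
class ProcessEvent:
    """An operator-logged bioprocess event acting on a time window.

    ``magnitude`` is kind-specific: a death-stress weight for
    ``gas_blocking``/``oxygen_depletion``/``substrate_limitation``, the
    substrate added in g/L for ``medium_addition``, the restored dissolved
    oxygen setpoint (% sat) for ``oxygen_resupply`` and the feed substrate
    concentration (g/L) for ``feed_start``.
    """

    name: str
    kind: str
    start: float
    end: float
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if not (0.0 <= self.start < self.end):
            raise ValueError(f"event {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end}]")

    def active(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class ClassCountSeries:
    """Per-timepoint mean detections/image for each of the six classes.

    ``mean_counts`` holds the reported (post-classifier) means in the
    canonical :data:`CLASS_COLUMNS` order; ``mean_true`` the means of the
    underlying true classes when known (synthetic data), else ``None``.
    Raw per-image count arrays of shape ``(n_times, 6, n_images)`` are kept
    when available so downstream code can re-aggregate.
    """

    time: np.ndarray
    mean_counts: np.ndarray
    n_images: np.ndarray
    mean_true: np.ndarray | None = None
    raw_reported: np.ndarray | None = None
    raw_true: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        self.n_images = np.asarray(self.n_images, dtype=int)
        if self.mean_counts.shape != (self.time.size, len(CLASS_COLUMNS)):
            raise ValueError(
                f"mean_counts shape {self.mean_counts.shape} does not match "
                f"({self.time.size}, {len(CLASS_COLUMNS)})"
            )
        if self.n_images.shape != self.time.shape:
            raise ValueError("n_images must have one entry per time point")
        if np.any(self.mean_counts < 0):
            raise ValueError("mean counts must be non-negative")
        if np.any(self.n_images < 1):
            raise ValueError("each point needs at least one image")

    @classmethod
    def from_raw_counts(
        cls,
        time: Sequence[float],
        raw_reported: np.ndarray,
        *,
        min_images: int = 1000,
        seed: int | None = None,
    ) -> "ClassCountSeries":
        """Aggregate raw per-image counts from frames into a series.

        Enforces the aggregation floor used when points are built from raw
        micrographs (default 1000 images per experimental point).
        """
        raw = np.asarray(raw_reported)
        if raw.ndim != 3 or raw.shape[1] != len(CLASS_COLUMNS):
            raise ValueError("raw_reported must have shape (n_times, 6, n_images)")
        if raw.shape[2] < min_images:
            raise ValueError(
                f"each point must aggregate at least {min_images} images, got {raw.shape[2]}"
            )
        return cls(
            time=np.asarray(time, dtype=float),
            mean_counts=raw.mean(axis=2),
            n_images=np.full(len(time), raw.shape[2], dtype=int),
            raw_reported=raw,
            seed=seed,
        )
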
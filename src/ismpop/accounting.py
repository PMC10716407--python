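"""Population accounting: counts → densities, viability, smoothing, events.

The monitoring computation is a linear calibration: the mean number of
in-focus cells per image y(t) maps to a culture density X(t) = α·y(t),
with α (image/mL) the inverse of the optical probe volume.  Viable cells
are the sum of plain viable, bulge-displaying viable and paired cells;
dead/dying cells the sum of apoptotic, necrotic and late-necrotic cells;
viability is the viable share of the total, in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CLASS_COLUMNS,
    DEAD_COLUMNS,
    VIABLE_COLUMNS,
    ClassCountSeries,
    ProcessEvent,
)

__all__ = [
    "CalibrationModel",
    "DensitySeries",
    "counts_to_density",
    "pool_and_viability",
    "moving_average",
    "relative_change",
    "build_event_table",
    "dilution_rate",
    "residence_time_days",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Probe-volume calibration X = α·y with its fit statistics."""

    alpha: float       # image/mL
    r: float           # Pearson correlation of (y, X)
    r2: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def to_dict(self) -> dict:
        return {"alpha_image_per_ml": self.alpha, "r": self.r, "r2": self.r2}


def counts_to_density(y, alpha: float):
    """Convert mean cells/image into cell/mL via the linear model X = α·y."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("counts per image must be >= 0")
    out = alpha * y_arr
    return float(out) if np.isscalar(y) or out.ndim == 0 else out


def pool_and_viability(densities) -> dict:
    """Pool six per-class densities into viable/dead totals and viability %.

    ``densities`` may be a mapping keyed by the canonical column names or a
    length-6 sequence in canonical order.  With zero total density the
    viability is undefined and reported as NaN (never 0 or 100).
    """
    if isinstance(densities, dict):
        try:
            d = np.array([densities[c] for c in CLASS_COLUMNS], dtype=float)
        except KeyError as exc:
            raise KeyError(f"missing class density {exc}") from exc
    else:
        d = np.asarray(densities, dtype=float)
        if d.shape != (len(CLASS_COLUMNS),):
            raise ValueError("expected six per-class densities")
    if np.any(d < 0):
        raise ValueError("densities must be >= 0")
    viable = float(d[list(VIABLE_COLUMNS)].sum())
    dead = float(d[list(DEAD_COLUMNS)].sum())
    total = viable + dead
    viability = 100.0 * viable / total if total > 0 else float("nan")
    return {
        "viable_total": viable,
        "dead_total": dead,
        "total": total,
        "viability": viability,
    }


@dataclass
class DensitySeries:
    """Per-class densities over time with derived totals and viability."""

    time: np.ndarray            # h
    densities: np.ndarray       # (n, 6) cell/mL, canonical column order

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (self.time.size, len(CLASS_COLUMNS)):
            raise ValueError("densities must have shape (n_times, 6)")
        if np.any(self.densities < 0):
            raise ValueError("densities must be >= 0")

    @classmethod
    def from_counts(cls, counts: ClassCountSeries, alpha: float) -> "DensitySeries":
        return cls(time=counts.time, densities=counts_to_density(counts.mean_counts, alpha))

    @property
    def viable_total(self) -> np.ndarray:
        return self.densities[:, list(VIABLE_COLUMNS)].sum(axis=1)

    @property
    def dead_total(self) -> np.ndarray:
        return self.densities[:, list(DEAD_COLUMNS)].sum(axis=1)

    @property
    def total(self) -> np.ndarray:
        return self.densities.sum(axis=1)

    @property
    def viability(self) -> np.ndarray:
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, 100.0 * self.viable_total / tot, np.nan)

    def smoothed(self, window: int) -> "DensitySeries":
        sm = np.column_stack(
            [moving_average(self.densities[:, j], window) for j in range(len(CLASS_COLUMNS))]
        )
        return DensitySeries(time=self.time.copy(), densities=sm)

    def class_column(self, name: str) -> np.ndarray:
        return self.densities[:, CLASS_COLUMNS.index(name)]

    def value_at(self, t: float, column: int, mode: str = "nearest") -> float:
        if t < self.time[0] or t > self.time[-1]:
            raise ValueError(
                f"time {t} outside series range [{self.time[0]}, {self.time[-1]}]"
            )
        if mode == "nearest":
            i = int(np.argmin(np.abs(self.time - t)))
            return float(self.densities[i, column])
        if mode == "interpolate":
            return float(np.interp(t, self.time, self.densities[:, column]))
        raise ValueError(f"unknown sampling mode {mode!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.densities, columns=list(CLASS_COLUMNS))
        df.insert(0, "time_h", self.time)
        df["viable_total"] = self.viable_total
        df["dead_total"] = self.dead_total
        df["total"] = self.total
        df["viability"] = self.viability
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DensitySeries":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in ("time_h", *CLASS_COLUMNS) if c not in df.columns]
        if missing:
            raise ValueError(f"density CSV missing columns: {missing}")
        return cls(time=df["time_h"].to_numpy(), densities=df[list(CLASS_COLUMNS)].to_numpy())


def moving_average(values, window: int, mode: str = "shrink") -> np.ndarray:
    """Centred moving mean used to smooth per-class density curves.

    ``window`` must be odd.  With ``mode='shrink'`` (default) the window
    shrinks near the edges; with ``mode='wrap'`` the series is padded
    periodically, which preserves the series mean exactly.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    v = np.asarray(values, dtype=float)
    if window == 1:
        return v.copy()
    if mode == "shrink":
        return (
            pd.Series(v).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
    if mode == "wrap":
        half = window // 2
        padded = np.concatenate([v[-half:], v, v[:half]])
        kernel = np.ones(window) / window
        return np.convolve(padded, kernel, mode="valid")
    raise ValueError(f"unknown moving-average mode {mode!r}")


def relative_change(start: float, end: float) -> int:
    """Integer percent change (end − start)/start, rounded half away from zero."""
    if start <= 0:
        raise ValueError("start density must be > 0 for a relative change")
    pct = (end - start) / start * 100.0
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct)) if pct != 0 else 0


def build_event_table(
    series: DensitySeries,
    events: Sequence[ProcessEvent],
    mode: str = "nearest",
) -> pd.DataFrame:
    """One row per event × class with start/end densities and percent change.

    Densities are read off the series at the event's start/end ages, at the
    nearest grid point by default (linear interpolation optional).
    """
    rows = []
    for ev in events:
        for j, col in enumerate(CLASS_COLUMNS):
            start_d = series.value_at(ev.start, j, mode)
            end_d = series.value_at(ev.end, j, mode)
            rows.append(
                {
                    "event": ev.name,
                    "class": col,
                    "start_h": ev.start,
                    "end_h": ev.end,
                    "start_density": start_d,
                    "end_density": end_d,
                    "relative_change_pct": relative_change(start_d, end_d)
                    if start_d > 0
                    else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event", "class", "start_h", "end_h",
            "start_density", "end_density", "relative_change_pct",
        ],
    )


def dilution_rate(harvest_l_per_day: float, working_volume_l: float) -> float:
    """Continuous-culture dilution rate D (1/h) from harvest flow and volume."""
    if harvest_l_per_day <= 0 or working_volume_l <= 0:
        raise ValueError("harvest flow and working volume must be > 0")
    return harvest_l_per_day / 24.0 / working_volume_l


def residence_time_days(harvest_l_per_day: float, working_volume_l: float) -> float:
    """Mean medium residence time 1/D, in days."""
    if harvest_l_per_day <= 0 or working_volume_l <= 0:
        raise ValueError("harvest flow and working volume must be > 0")
    return working_volume_l / harvest_l_per_day
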
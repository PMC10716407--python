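"""Synthetic ISM data generation.

Everything the monitoring analysis consumes can be generated here:

* :func:`simulate_bioprocess` — a deterministic six-pool kinetic model of a
  hybridoma batch → continuous culture (Monod growth, feast/famine bulge
  transition, stress-driven apoptosis/necrosis, dilution/washout);
* :func:`sample_ism_counts` — Poisson probe-volume sampling of per-image
  cell counts, with an optional classifier-confusion overlay;
* :func:`generate_offline_reference` — trypan-blue-like offline density and
  viability samples with the assay's characteristic error structure;
* :func:`render_micrograph` — 8-bit grayscale frames with per-class
  morphology templates, defocus blur, exposure offsets and ground-truth
  annotations of the in-focus cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    CLASS_COLUMNS,
    CLASS_ID_TO_COLUMN,
    COLUMN_CLASS_IDS,
    DEAD_COLUMNS,
    VIABLE_COLUMNS,
    BoundingBox,
    CellClass,
    ClassCountSeries,
    ProcessEvent,
)

__all__ = [
    "KineticParameters",
    "InitialState",
    "BioprocessTrajectory",
    "OpticsParameters",
    "OfflineSample",
    "OfflineNoise",
    "ConfusionSpec",
    "CellSpec",
    "IntegrationError",
    "simulate_bioprocess",
    "growth_influx",
    "sample_ism_counts",
    "generate_offline_reference",
    "render_micrograph",
    "sample_scene",
    "single_cell_frame",
]


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integrator produces an invalid state."""


# --------------------------------------------------------------------------
# Kinetics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the six-pool culture model.

    The maximal specific growth rate (0.04/h) and the continuous-phase
    dilution rate (0.0125/h) are the operating values of the hybridoma
    process this generator emulates; the remaining constants shape the
    qualitative event responses (bulge transitions, stress-driven death)
    and have no measured counterpart.
    """

    mu_max: float = 0.04          # 1/h, maximal specific growth rate
    Ks: float = 0.5               # g/L, substrate half-saturation
    Ko: float = 3.0               # % sat, oxygen half-saturation
    k_bulge_on: float = 0.15      # 1/h, extra viable -> bulged rate under the signal
    k_bulge_off: float = 0.15     # 1/h, extra bulged -> viable rate once it clears
    k_bulge_on_base: float = 0.10   # 1/h, baseline exchange toward the bulged state
    k_bulge_off_base: float = 0.12  # 1/h, baseline exchange back
    k_apo_base: float = 0.001     # 1/h, baseline apoptosis
    k_apo_stress: float = 0.008   # 1/h per unit stress weight
    k_nec_base: float = 0.001     # 1/h, baseline necrosis
    k_nec_stress: float = 0.004   # 1/h per unit stress weight
    k_late: float = 0.02          # 1/h, necrotic -> late necrotic
    k_pair: float = 0.35          # fraction of division flux visible as pairs
    k_split: float = 0.12         # 1/h, pair -> 2 viable singles
    k_lysis: float = 0.01         # 1/h, late necrotic disappearance
    D: float = 0.0                # 1/h, dilution rate (0 batch, 0.0125 continuous)
    # substrate / oxygen balance plumbing
    yield_cells_per_g: float = 2.2e5   # cells/mL produced per g/L substrate
    o2_rate: float = 2.0               # 1/h, DO relaxation toward its setpoint
    o2_setpoint: float = 30.0          # % sat, controller setpoint
    s_lim: float = 0.25                # g/L, famine threshold
    o_lim: float = 5.0                 # % sat, hypoxia threshold
    ff_rel_threshold: float = 0.25     # 1/h, |dS/dt|/S feast/famine trigger
    s_feed_default: float = 4.5        # g/L, feed substrate if no event magnitude

    def __post_init__(self) -> None:
        for name in (
            "mu_max", "Ks", "Ko", "k_bulge_on", "k_bulge_off",
            "k_bulge_on_base", "k_bulge_off_base", "k_apo_base",
            "k_apo_stress", "k_nec_base", "k_nec_stress", "k_late", "k_pair",
            "k_split", "k_lysis", "D", "o2_rate", "s_lim", "o_lim",
            "ff_rel_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"kinetic parameter {name} must be >= 0")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")
        if self.yield_cells_per_g <= 0:
            raise ValueError("yield_cells_per_g must be > 0")


@dataclass(frozen=True)
class InitialState:
    """Initial per-class densities (cell/mL), substrate (g/L) and DO (% sat)."""

    viable: float = 1.66e5
    viable_bulges: float = 1.59e5
    pair: float = 1.8e4
    apoptotic: float = 4.1e4
    necrotic: float = 1.57e4
    necrotic_late: float = 2.0e3
    substrate: float = 4.5
    dissolved_oxygen: float = 30.0

    def as_vector(self) -> np.ndarray:
        v = np.array(
            [self.viable, self.viable_bulges, self.pair, self.apoptotic,
             self.necrotic, self.necrotic_late, self.substrate,
             self.dissolved_oxygen],
            dtype=float,
        )
        if np.any(v[:6] < 0) or v[6] < 0 or v[7] < 0:
            raise ValueError("initial densities, substrate and DO must be >= 0")
        return v


@dataclass
class BioprocessTrajectory:
    """Forward-integrated culture state on a uniform time grid."""

    times: np.ndarray                 # h
    densities: np.ndarray             # (n, 6) cell/mL in CLASS_COLUMNS order
    substrate: np.ndarray             # g/L
    dissolved_oxygen: np.ndarray      # % sat

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.dissolved_oxygen = np.asarray(self.dissolved_oxygen, dtype=float)
        n = self.times.size
        if self.densities.shape != (n, len(CLASS_COLUMNS)):
            raise ValueError("densities must have shape (n_times, 6)")
        if self.substrate.shape != (n,) or self.dissolved_oxygen.shape != (n,):
            raise ValueError("substrate and DO must match the time grid")
        if np.any(self.densities < 0):
            raise ValueError("densities must be >= 0 at all times")

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
        """% viable of total; NaN where the total density is zero."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(tot > 0, 100.0 * self.viable_total / tot, np.nan)
        return v

    def interpolate(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated per-class densities at time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError(
                f"time(s) outside trajectory range [{self.times[0]}, {self.times[-1]}]"
            )
        out = np.column_stack(
            [np.interp(t, self.times, self.densities[:, j]) for j in range(len(CLASS_COLUMNS))]
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.densities, columns=list(CLASS_COLUMNS))
        df.insert(0, "time_h", self.times)
        df["substrate"] = self.substrate
        df["do"] = self.dissolved_oxygen
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BioprocessTrajectory":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in ("time_h", *CLASS_COLUMNS) if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        n = len(df)
        return cls(
            times=df["time_h"].to_numpy(),
            densities=df[list(CLASS_COLUMNS)].to_numpy(),
            substrate=df["substrate"].to_numpy() if "substrate" in df else np.zeros(n),
            dissolved_oxygen=df["do"].to_numpy() if "do" in df else np.zeros(n),
        )


def _event_terms(events: Sequence[ProcessEvent], t: float, params: KineticParameters):
    """Collect event-driven modifiers active at time t."""
    w_apo = 0.0
    w_nec = 0.0
    famine_forced = False
    addition_rate = 0.0            # g/L/h
    o2_target = params.o2_setpoint
    diluting = False
    s_feed = params.s_feed_default
    has_feed_event = any(e.kind == "feed_start" for e in events)
    for e in events:
        if not e.active(t):
            continue
        if e.kind == "gas_blocking":
            w_apo += e.magnitude
            w_nec += e.magnitude
        elif e.kind == "medium_addition":
            addition_rate += e.magnitude / (e.end - e.start)
        elif e.kind == "substrate_limitation":
            famine_forced = True
            w_nec += e.magnitude
        elif e.kind == "oxygen_depletion":
            o2_target = 0.0
            w_apo += e.magnitude
            w_nec += 0.6 * e.magnitude
        elif e.kind == "oxygen_resupply":
            o2_target = e.magnitude if e.magnitude > 0 else params.o2_setpoint
        elif e.kind == "feed_start":
            diluting = True
            if e.magnitude > 0:
                s_feed = e.magnitude
    # With no feed_start event in the schedule, a nonzero D means the whole
    # run is continuous (chemostat from t=0).
    if not has_feed_event and params.D > 0:
        diluting = True
    return w_apo, w_nec, famine_forced, addition_rate, o2_target, diluting, s_feed


def _derivative(t: float, x: np.ndarray, params: KineticParameters,
                events: Sequence[ProcessEvent]) -> np.ndarray:
    v, b, p, a, n, l, S, O = x
    S = max(S, 0.0)
    O = max(O, 0.0)
    (w_apo, w_nec, famine_forced, addition_rate,
     o2_target, diluting, s_feed) = _event_terms(events, t, params)

    # Monod growth on substrate and dissolved oxygen (half-saturation 0 means
    # the factor is saturated whenever the resource is present).
    fS = 1.0 if (params.Ks == 0 and S > 0) else (S / (params.Ks + S) if (params.Ks + S) > 0 else 0.0)
    fO = 1.0 if (params.Ko == 0 and O > 0) else (O / (params.Ko + O) if (params.Ko + O) > 0 else 0.0)
    mu = params.mu_max * fS * fO
    G = mu * (v + b)                       # division flux, new cells per mL per h

    D_eff = params.D if diluting else 0.0

    # substrate balance (needed before the feast/famine signal)
    dS = -G / params.yield_cells_per_g + addition_rate
    if diluting:
        dS += params.D * (s_feed - S)

    famine = famine_forced or (S < params.s_lim)
    feast = S > 0 and abs(dS) / max(S, 1e-9) > params.ff_rel_threshold
    signal = famine or feast

    if famine:
        w_nec += 1.0
    if O < params.o_lim:
        w_apo += 1.0
        w_nec += 0.5

    k_apo = params.k_apo_base + params.k_apo_stress * w_apo
    k_nec = params.k_nec_base + params.k_nec_stress * w_nec

    # two-way viable <-> bulged exchange; the feast/famine signal raises the
    # on-rate, its clearing raises the off-rate (rapid return to normal)
    on_rate = params.k_bulge_on_base + (params.k_bulge_on if signal else 0.0)
    off_rate = params.k_bulge_off_base + (0.0 if signal else params.k_bulge_off)
    bulge_flux = on_rate * v - off_rate * b

    dv = ((1.0 - params.k_pair) * G - params.k_pair * G
          + 2.0 * params.k_split * p - bulge_flux
          - (k_apo + k_nec) * v - D_eff * v)
    db = bulge_flux - (k_apo + k_nec) * b - D_eff * b
    dp = params.k_pair * G - params.k_split * p - D_eff * p
    da = k_apo * (v + b) - D_eff * a
    dn = k_nec * (v + b) - params.k_late * n - D_eff * n
    dl = params.k_late * n - params.k_lysis * l - D_eff * l
    dO = params.o2_rate * (o2_target - O)

    return np.array([dv, db, dp, da, dn, dl, dS, dO])


def growth_influx(x: np.ndarray, params: KineticParameters,
                  events: Sequence[ProcessEvent], t: float) -> float:
    """Rate at which new countable cells enter the observed population.

    A fraction ``k_pair`` of division events is observed as a pair (one
    detection unit holding mother and daughter); the daughter only becomes
    countable when the pair splits, so the influx into the summed per-class
    density is ``(1 - k_pair)·µ·(v+b) + k_split·p``.  With ``k_lysis = 0``
    and no dilution the time derivative of the summed density equals this
    influx exactly.
    """
    v, b, p = x[0], x[1], x[2]
    S = max(x[6], 0.0)
    O = max(x[7], 0.0)
    fS = 1.0 if (params.Ks == 0 and S > 0) else (S / (params.Ks + S) if (params.Ks + S) > 0 else 0.0)
    fO = 1.0 if (params.Ko == 0 and O > 0) else (O / (params.Ko + O) if (params.Ko + O) > 0 else 0.0)
    mu = params.mu_max * fS * fO
    return (1.0 - params.k_pair) * mu * (v + b) + params.k_split * p


def simulate_bioprocess(
    params: KineticParameters,
    events: Sequence[ProcessEvent],
    init: InitialState,
    t_end: float,
    dt: float = 0.05,
) -> BioprocessTrajectory:
    """Integrate the culture model with fixed-step RK4.

    Raises
    ------
    ValueError
        For non-positive ``dt``/``t_end`` or negative initial state.
    IntegrationError
        If a step drives any state meaningfully negative (the step size is
        too large for the configured rates); the state is never silently
        clipped.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x = init.as_vector()
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 8))
    out[0] = x
    scale = max(1.0, float(np.max(np.abs(x))))
    for i in range(n_steps):
        t = times[i]
        k1 = _derivative(t, x, params, events)
        k2 = _derivative(t + dt / 2, x + dt / 2 * k1, params, events)
        k3 = _derivative(t + dt / 2, x + dt / 2 * k2, params, events)
        k4 = _derivative(t + dt, x + dt * k3, params, events)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        scale = max(scale, float(np.max(np.abs(x))))
        if np.any(x < -1e-9 * scale):
            raise IntegrationError(
                f"negative state at t={times[i + 1]:.3f} h (min {x.min():.3e}); "
                "reduce dt or the rate constants"
            )
        # snap floating-point dust (|x| < 1e-9·scale) to exactly zero
        x[(x < 0)] = 0.0
        out[i + 1] = x
    return BioprocessTrajectory(
        times=times,
        densities=out[:, :6],
        substrate=out[:, 6],
        dissolved_oxygen=out[:, 7],
    )


# --------------------------------------------------------------------------
# Probe-volume count sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic 6×6 matrix: P(reported class j | true class i).

    Rows/columns follow the canonical :data:`~ismpop.core.CLASS_COLUMNS`
    order.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (6, 6):
            raise ValueError("confusion matrix must be 6x6")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("confusion entries must lie in [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("confusion matrix rows must sum to 1")

    @classmethod
    def identity(cls) -> "ConfusionSpec":
        return cls(np.eye(6))

    @classmethod
    def symmetric_swap(cls, class_a: int, class_b: int, rate: float) -> "ConfusionSpec":
        """Identity except classes a and b are mutually confused at ``rate``.

        Used to emulate the characteristic viable ↔ viable-with-bulges
        ambiguity of morphological classifiers.
        """
        m = np.eye(6)
        ia, ib = CLASS_ID_TO_COLUMN[class_a], CLASS_ID_TO_COLUMN[class_b]
        m[ia, ia] = 1.0 - rate
        m[ia, ib] = rate
        m[ib, ib] = 1.0 - rate
        m[ib, ia] = rate
        return cls(m)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.matrix, np.eye(6)))


def sample_ism_counts(
    trajectory: BioprocessTrajectory,
    alpha: float,
    n_images_per_point: int,
    confusion: ConfusionSpec | None = None,
    seed: int = 0,
    sample_times: Sequence[float] | None = None,
) -> ClassCountSeries:
    """Draw per-image in-focus counts from the probe-volume model.

    Each image observes a fixed probe volume ``1/alpha`` mL, so the number
    of class-``c`` cells in one image is Poisson with mean
    ``density_c / alpha``, independent across images and classes.  Each
    counted cell's reported class is then re-drawn from the confusion
    matrix row of its true class.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_images_per_point < 1:
        raise ValueError("n_images_per_point must be >= 1")
    confusion = confusion or ConfusionSpec.identity()
    rng = np.random.default_rng(seed)
    if sample_times is None:
        times = trajectory.times
        dens = trajectory.densities
    else:
        times = np.asarray(sample_times, dtype=float)
        dens = trajectory.interpolate(times)

    T = times.size
    raw_true = np.empty((T, 6, n_images_per_point), dtype=np.int64)
    for j in range(6):
        lam = dens[:, j][:, None] / alpha
        raw_true[:, j, :] = rng.poisson(np.broadcast_to(lam, (T, n_images_per_point)))

    if confusion.is_identity:
        raw_reported = raw_true.copy()
    else:
        raw_reported = np.zeros_like(raw_true)
        for j in range(6):
            row = confusion.matrix[j]
            # multinomial thinning of each image's true count for class j
            reported = rng.multinomial(raw_true[:, j, :].ravel(), row)
            raw_reported += reported.reshape(T, n_images_per_point, 6).transpose(0, 2, 1)

    return ClassCountSeries(
        time=times,
        mean_counts=raw_reported.mean(axis=2),
        n_images=np.full(T, n_images_per_point),
        mean_true=raw_true.mean(axis=2),
        raw_reported=raw_reported,
        raw_true=raw_true,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Offline (trypan-blue-like) reference samples
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OfflineSample:
    """One offline reference measurement."""

    time: float          # h
    density: float       # cell/mL (total)
    viability: float     # %

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not (0.0 <= self.viability <= 100.0):
            raise ValueError("viability must lie in [0, 100]")


@dataclass(frozen=True)
class OfflineNoise:
    """Error structure of the dye-exclusion reference assay.

    Viability error is additive Gaussian (default sd 5 percentage points),
    inflated to a configured coefficient of variation (default 18.8%) once
    the true viability drops below ``low_viab_threshold`` (default 28%),
    where dying cells stain ambiguously and few cells are counted.  Density
    error is multiplicative lognormal with relative sd
    ``density_rel_sd`` (default 0.20).
    """

    viability_sd_pct: float = 5.0
    density_rel_sd: float = 0.20
    low_viab_cv: float = 18.8       # % CV applied below the threshold
    low_viab_threshold: float = 28.0  # % viability

    @classmethod
    def noiseless(cls) -> "OfflineNoise":
        return cls(0.0, 0.0, 0.0, 0.0)


def generate_offline_reference(
    trajectory: BioprocessTrajectory,
    sample_times: Sequence[float],
    noise: OfflineNoise | None = None,
    seed: int = 0,
) -> list[OfflineSample]:
    """Sample offline reference points from the true trajectory."""
    noise = noise or OfflineNoise()
    rng = np.random.default_rng(seed)
    times = np.asarray(sample_times, dtype=float)
    dens = trajectory.interpolate(times)     # raises on out-of-range times
    total = dens.sum(axis=1)
    viable = dens[:, list(VIABLE_COLUMNS)].sum(axis=1)
    out: list[OfflineSample] = []
    for t, x, v_tot in zip(times, total, viable):
        viab = 100.0 * v_tot / x if x > 0 else 0.0
        sd = noise.viability_sd_pct
        if viab < noise.low_viab_threshold:
            sd = noise.low_viab_cv / 100.0 * viab
        viab_s = viab + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        viab_s = float(min(100.0, max(0.0, viab_s)))
        if noise.density_rel_sd > 0:
            sigma = math.sqrt(math.log(1.0 + noise.density_rel_sd ** 2))
            x_s = x * math.exp(rng.normal(0.0, sigma) - sigma ** 2 / 2.0)
        else:
            x_s = x
        out.append(OfflineSample(time=float(t), density=max(0.0, float(x_s)), viability=viab_s))
    return out


# --------------------------------------------------------------------------
# Micrograph rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsParameters:
    """Geometry and photometry of the simulated in situ microscope.

    The frame is 1392 × 1040 px imaging a 0.22 × 0.16 mm² object field,
    i.e. ≈ 0.158 µm/px.  Cells beyond half the depth of field are rendered
    defocused and are not annotated; cells on the illumination side of the
    focal plane (z > 0) appear brighter, those behind it darker.
    """

    frame_width: int = 1392
    frame_height: int = 1040
    pixel_size: float = 0.158          # µm/px
    cell_diameter_mean: float = 15.0   # µm
    cell_diameter_sd: float = 1.5      # µm
    depth_of_field: float = 6.0        # µm
    blur_per_um: float = 0.6           # px of Gaussian sigma per µm defocus
    bright_offset: float = 25.0        # grey levels for z > 0 (lensing side)
    dark_offset: float = 25.0          # grey levels for z < 0
    background_level: float = 128.0
    background_noise_sd: float = 3.0
    cell_contrast: float = 22.0        # interior grey-level deficit vs background
    rim_depth: float = 45.0            # extra darkening of the cell rim
    bulge_amplitude: float = 0.20      # radial modulation of the bulged template
    bulge_lobes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.depth_of_field <= 0:
            raise ValueError("depth_of_field must be > 0")
        for name in ("background_level", "bright_offset", "dark_offset"):
            if not (0 <= getattr(self, name) <= 255):
                raise ValueError(f"{name} must be a grey level in [0, 255]")


@dataclass(frozen=True)
class CellSpec:
    """One cell to render: class, position, defocus, size and texture seed."""

    cell_class: CellClass | int
    cx: float            # px
    cy: float            # px
    z: float = 0.0       # µm; signed offset from the focal plane
    diameter: float = 15.0   # µm
    texture_seed: int = 0


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  scale: float, amp: float) -> np.ndarray:
    """Band-limited Gaussian texture with unit-std normalization."""
    raw = rng.normal(0.0, 1.0, shape)
    f = ndimage.gaussian_filter(raw, scale)
    s = f.std()
    if s < 1e-12:
        return np.zeros(shape)
    return f * (amp / s)


def _radius_profile(cls: int, rng: np.random.Generator,
                    optics: OpticsParameters) -> Callable[[np.ndarray], np.ndarray]:
    """Radial boundary modulation r(θ)/r0 for the single-body templates."""
    if cls == CellClass.VIABLE:
        a = rng.uniform(0.01, 0.03)
        ph = rng.uniform(0, 2 * math.pi)
        return lambda th: 1.0 + a * np.cos(3 * th + ph)
    if cls == CellClass.APOPTOTIC:
        # shrunken, markedly irregular contour (low-order lobes + roughness)
        a2 = rng.uniform(0.15, 0.21)
        a3 = rng.uniform(0.12, 0.18)
        a7 = rng.uniform(0.05, 0.08)
        p2, p3, p7 = rng.uniform(0, 2 * math.pi, 3)
        return lambda th: (1.0 + a2 * np.cos(2 * th + p2) + a3 * np.cos(3 * th + p3)
                           + a7 * np.cos(7 * th + p7))
    if cls in (CellClass.NECROTIC, CellClass.NECROTIC_LATE):
        # cytoplasmic swelling: almost perfect roundness
        a = rng.uniform(0.005, 0.015)
        ph = rng.uniform(0, 2 * math.pi)
        return lambda th: 1.0 + a * np.cos(4 * th + ph)
    if cls == CellClass.VIABLE_BULGES:
        amp = optics.bulge_amplitude
        n = optics.bulge_lobes
        ph = rng.uniform(0, 2 * math.pi)
        a_low = rng.uniform(0.01, 0.03)
        return lambda th: 1.0 + amp * np.cos(n * th + ph) + a_low * np.cos(2 * th)
    raise ValueError(f"no single-body radius profile for class {cls}")


def _render_cell_patch(spec: CellSpec, optics: OpticsParameters):
    """Return (patch colour, patch alpha, x0, y0, annotation mask) in px."""
    cls = int(spec.cell_class)
    rng = np.random.default_rng(spec.texture_seed)
    r0 = spec.diameter / 2.0 / optics.pixel_size          # px
    excess = max(0.0, abs(spec.z) - optics.depth_of_field / 2.0)
    sigma_blur = optics.blur_per_um * excess
    if cls == CellClass.PAIR:
        r_sub = 0.80 * r0
        extent = r_sub * 2.0 + 0.75 * r_sub
    else:
        extent = r0 * 1.35
    pad = int(math.ceil(extent + 3 * sigma_blur + 4))
    size = 2 * pad + 1
    yy, xx = np.mgrid[-pad:pad + 1, -pad:pad + 1].astype(float)

    edge_w = 1.2   # px, smoothstep half-width of the membrane edge

    if cls == CellClass.PAIR:
        axis = rng.uniform(0, 2 * math.pi)
        sep = 0.75 * r_sub
        cx1, cy1 = sep * math.cos(axis), sep * math.sin(axis)
        d1 = np.hypot(xx - cx1, yy - cy1)
        d2 = np.hypot(xx + cx1, yy + cy1)
        signed = np.minimum(d1, d2) - r_sub
    else:
        prof = _radius_profile(cls, rng, optics)
        rr = np.hypot(xx, yy)
        th = np.arctan2(yy, xx)
        signed = rr - r0 * prof(th)

    alpha = np.clip(0.5 - signed / (2 * edge_w), 0.0, 1.0)
    rim = np.exp(-((signed + 1.5) ** 2) / (2 * 2.0 ** 2))

    interior = optics.background_level - optics.cell_contrast
    if cls in (CellClass.VIABLE, CellClass.PAIR):
        tex = _smooth_noise(rng, (size, size), 2.5, 1.2)
    elif cls == CellClass.VIABLE_BULGES:
        # slightly less homogeneous than plain viable cells
        tex = _smooth_noise(rng, (size, size), 2.5, 2.8)
    else:  # apoptotic / necrotic / late necrotic: strong inhomogeneity
        tex = _smooth_noise(rng, (size, size), 1.8, 14.0)

    # keep the inhomogeneity cytoplasmic: taper it to zero at the membrane
    # so strong speckle cannot eat into the segmented contour
    tex = tex * np.clip((-signed - 3.0) / 5.0, 0.0, 1.0)

    colour = interior + tex - optics.rim_depth * rim

    if cls == CellClass.APOPTOTIC:
        # a few bright vesicle-like inclusions (apoptotic bodies)
        for _ in range(rng.integers(2, 5)):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0.1, 0.5) * r0
            vx, vy = rad * math.cos(ang), rad * math.sin(ang)
            vr = rng.uniform(1.5, 2.8)
            colour += 20.0 * np.exp(-((xx - vx) ** 2 + (yy - vy) ** 2) / (2 * vr ** 2))

    if cls == CellClass.NECROTIC_LATE:
        # membrane rupture: over one arc the rim and edge contrast fade away
        arc_c = rng.uniform(0, 2 * math.pi)
        arc_hw = math.radians(rng.uniform(35.0, 50.0))
        th_all = np.arctan2(yy, xx)
        dang = np.angle(np.exp(1j * (th_all - arc_c)))
        fade = np.clip((np.abs(dang) - arc_hw) / math.radians(18.0), 0.0, 1.0)
        # fade: 0 inside the ruptured arc, 1 elsewhere; restore the rim
        # darkening inside the arc so the border loses contrast there
        colour += optics.rim_depth * rim * (1.0 - fade)
        # soften the edge itself: wide local feathering of alpha inside the arc
        soft = np.clip(0.5 - signed / (2 * 6.0), 0.0, 1.0)
        alpha = alpha * fade + soft * (1.0 - fade) * 0.85

    # exposure offset depends on the side of the focal plane
    if spec.z > 0:
        colour = colour + optics.bright_offset * min(1.0, spec.z / optics.depth_of_field)
    elif spec.z < 0:
        colour = colour - optics.dark_offset * min(1.0, -spec.z / optics.depth_of_field)

    ann_mask = alpha > 0.5

    premult = colour * alpha
    if sigma_blur > 0:
        premult = ndimage.gaussian_filter(premult, sigma_blur)
        alpha = ndimage.gaussian_filter(alpha, sigma_blur)

    x0 = int(round(spec.cx)) - pad
    y0 = int(round(spec.cy)) - pad
    return premult, alpha, x0, y0, ann_mask


def render_micrograph(
    cells: Sequence[CellSpec],
    optics: OpticsParameters,
) -> tuple[np.ndarray, list[tuple[int, BoundingBox]]]:
    """Render one 8-bit grayscale frame and the in-focus annotations.

    Cells with ``|z| > depth_of_field / 2`` are rendered blurred (blur
    growing with defocus) and excluded from the returned annotation list.
    Annotations are ``(class_id, BoundingBox)`` with normalized coordinates
    and top-left origin.  An empty cell list yields a background-only frame.
    """
    H, W = optics.frame_height, optics.frame_width
    rng_bg = np.random.default_rng(optics.seed)
    frame = np.full((H, W), float(optics.background_level))
    annotations: list[tuple[int, BoundingBox]] = []

    for spec in cells:
        if spec.diameter <= 0:
            raise ValueError("cell diameter must be > 0")
        premult, alpha, x0, y0, ann_mask = _render_cell_patch(spec, optics)
        ph, pw = alpha.shape
        fx0, fy0 = max(x0, 0), max(y0, 0)
        fx1, fy1 = min(x0 + pw, W), min(y0 + ph, H)
        if fx1 <= fx0 or fy1 <= fy0:
            continue
        px0, py0 = fx0 - x0, fy0 - y0
        sub_a = alpha[py0:py0 + (fy1 - fy0), px0:px0 + (fx1 - fx0)]
        sub_p = premult[py0:py0 + (fy1 - fy0), px0:px0 + (fx1 - fx0)]
        frame[fy0:fy1, fx0:fx1] = frame[fy0:fy1, fx0:fx1] * (1.0 - sub_a) + sub_p

        if abs(spec.z) <= optics.depth_of_field / 2.0:
            ys, xs = np.nonzero(ann_mask)
            if ys.size == 0:
                continue
            bx0, bx1 = x0 + xs.min(), x0 + xs.max() + 1
            by0, by1 = y0 + ys.min(), y0 + ys.max() + 1
            bx0, bx1 = max(bx0, 0), min(bx1, W)
            by0, by1 = max(by0, 0), min(by1, H)
            if bx1 <= bx0 or by1 <= by0:
                continue
            annotations.append(
                (
                    int(spec.cell_class),
                    BoundingBox(
                        cx=(bx0 + bx1) / 2.0 / W,
                        cy=(by0 + by1) / 2.0 / H,
                        w=(bx1 - bx0) / W,
                        h=(by1 - by0) / H,
                    ),
                )
            )

    frame += rng_bg.normal(0.0, optics.background_noise_sd, frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8), annotations


def sample_scene(
    densities: np.ndarray | Sequence[float],
    alpha: float,
    optics: OpticsParameters,
    rng: np.random.Generator,
    out_of_focus_factor: float = 1.5,
) -> list[CellSpec]:
    """Draw a random scene consistent with per-class densities (cell/mL).

    In-focus counts per class are Poisson with mean ``density/alpha``;
    additionally ``out_of_focus_factor`` times as many defocused cells are
    placed beyond the depth of field to emulate the blurred background
    population.
    """
    densities = np.asarray(densities, dtype=float)
    cells: list[CellSpec] = []
    margin = optics.cell_diameter_mean / optics.pixel_size
    dof = optics.depth_of_field

    def _place(cls: int, z: float) -> CellSpec:
        return CellSpec(
            cell_class=cls,
            cx=rng.uniform(margin, optics.frame_width - margin),
            cy=rng.uniform(margin, optics.frame_height - margin),
            z=z,
            diameter=max(6.0, rng.normal(optics.cell_diameter_mean, optics.cell_diameter_sd)),
            texture_seed=int(rng.integers(0, 2 ** 31 - 1)),
        )

    for j, col_cls in enumerate(COLUMN_CLASS_IDS):
        n_in = rng.poisson(densities[j] / alpha)
        for _ in range(n_in):
            cells.append(_place(col_cls, rng.uniform(-0.45, 0.45) * dof))
        n_out = rng.poisson(out_of_focus_factor * densities[j] / alpha)
        for _ in range(n_out):
            z = rng.uniform(1.0, 3.5) * dof * (1 if rng.random() < 0.5 else -1)
            cells.append(_place(col_cls, z))
    return cells


def single_cell_frame(
    cell_class: CellClass | int,
    optics: OpticsParameters,
    seed: int = 0,
    z: float = 0.0,
) -> tuple[np.ndarray, list[tuple[int, BoundingBox]]]:
    """Render one centred cell of the given class on an otherwise empty frame."""
    rng = np.random.default_rng(seed)
    spec = CellSpec(
        cell_class=cell_class,
        cx=optics.frame_width / 2.0 + rng.uniform(-20, 20),
        cy=optics.frame_height / 2.0 + rng.uniform(-20, 20),
        z=z,
        diameter=max(6.0, rng.normal(optics.cell_diameter_mean, optics.cell_diameter_sd)),
        texture_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    return render_micrograph([spec], replace(optics, seed=seed + 7919))
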
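"""Published operating data of the monitored hybridoma culture.

These constants are the inputs the monitoring analysis was demonstrated
on: the probe-volume calibration coefficient, the label-set bookkeeping of
the annotated micrograph database, the process geometry of the 5-L stirred
tank, and the per-class densities logged at the start and end of nine
operator-identified process events of the 145-h batch → continuous run.
They are data, not fitted quantities.
"""

from __future__ import annotations

import numpy as np

from .core import CLASS_COLUMNS

__all__ = [
    "ALPHA_IMAGE_PER_ML",
    "LABEL_COUNTS",
    "WORKING_VOLUME_L",
    "HARVEST_L_PER_DAY",
    "BATCH_END_H",
    "PROCESS_END_H",
    "DILUTION_RATE_PER_H",
    "EVENT_DENSITY_RECORDS",
    "reference_event_densities",
]

#: Probe-volume calibration: cell/mL = ALPHA · cells/image.
ALPHA_IMAGE_PER_ML: float = 3.2e6

#: Annotated cells per class (1..6) in the 4000-image labelling database.
LABEL_COUNTS: dict[int, int] = {1: 231, 2: 260, 3: 106, 4: 262, 5: 19, 6: 29}

WORKING_VOLUME_L: float = 5.0
HARVEST_L_PER_DAY: float = 1.5
BATCH_END_H: float = 75.5
PROCESS_END_H: float = 145.0
DILUTION_RATE_PER_H: float = 0.0125

#: Nine process events with per-class densities (cell/mL, canonical column
#: order: viable, viable_bulges, pair, apoptotic, necrotic, necrotic_late)
#: at the event's start and end culture ages.
EVENT_DENSITY_RECORDS: tuple[dict, ...] = (
    {
        "name": "gas_blocking_1_2", "kind": "gas_blocking",
        "start": 2.0, "end": 22.0,
        "start_densities": (2.67e5, 2.56e5, 2.88e4, 6.64e4, 2.53e4, 3.16e3),
        "end_densities": (3.85e5, 3.60e5, 9.79e4, 8.10e4, 4.00e4, 6.38e3),
    },
    {
        "name": "medium_addition_early", "kind": "medium_addition",
        "start": 24.0, "end": 26.0,
        "start_densities": (3.95e5, 3.69e5, 9.95e4, 8.25e4, 4.10e4, 7.10e3),
        "end_densities": (2.76e5, 5.64e5, 1.01e5, 9.00e4, 4.35e4, 7.20e3),
    },
    {
        "name": "medium_addition_late", "kind": "medium_addition",
        "start": 26.0, "end": 27.0,
        "start_densities": (2.76e5, 5.64e5, 1.01e5, 9.00e4, 4.35e4, 7.20e3),
        "end_densities": (4.81e5, 3.84e5, 1.11e5, 8.22e4, 4.11e4, 7.10e3),
    },
    {
        "name": "substrate_limitation_early", "kind": "substrate_limitation",
        "start": 34.0, "end": 44.0,
        "start_densities": (6.09e5, 4.05e5, 1.25e5, 1.01e5, 4.09e4, 6.50e3),
        "end_densities": (3.45e5, 7.81e5, 1.01e5, 1.03e5, 7.60e4, 1.52e4),
    },
    {
        "name": "substrate_limitation_late", "kind": "substrate_limitation",
        "start": 44.0, "end": 48.25,
        "start_densities": (3.45e5, 7.81e5, 1.01e5, 1.03e5, 7.60e4, 1.52e4),
        "end_densities": (7.45e5, 3.62e5, 1.03e5, 1.52e5, 1.43e5, 1.70e4),
    },
    {
        "name": "oxygen_depletion", "kind": "oxygen_depletion",
        "start": 48.25, "end": 56.0,
        "start_densities": (7.45e5, 3.62e5, 1.03e5, 1.52e5, 1.43e5, 1.70e4),
        "end_densities": (5.40e5, 3.80e5, 4.90e4, 3.00e5, 3.00e5, 2.00e4),
    },
    {
        "name": "oxygen_resupply", "kind": "oxygen_resupply",
        "start": 56.0, "end": 68.25,
        "start_densities": (5.40e5, 3.80e5, 4.90e4, 3.00e5, 3.00e5, 2.00e4),
        "end_densities": (2.58e5, 2.12e5, 9.00e3, 5.30e5, 2.58e5, 4.50e4),
    },
    {
        "name": "feed_start", "kind": "feed_start",
        "start": 75.5, "end": 86.0,
        "start_densities": (2.58e5, 2.12e5, 9.00e3, 5.30e5, 2.58e5, 4.50e4),
        "end_densities": (2.23e5, 1.98e5, 4.00e4, 5.79e5, 1.42e5, 3.00e4),
    },
    {
        "name": "continuous_phase", "kind": "feed_start",
        "start": 86.0, "end": 143.5,
        "start_densities": (2.23e5, 1.98e5, 4.00e4, 5.79e5, 1.42e5, 3.00e4),
        "end_densities": (9.10e4, 8.30e4, 9.00e3, 3.02e5, 3.80e4, 1.30e4),
    },
)


def reference_event_densities() -> tuple[np.ndarray, np.ndarray]:
    """Deduplicated (times, densities) grid through all event endpoints.

    Endpoint densities shared between consecutive events are identical in
    the source data, so the result is a single-valued series suitable for
    event-table reconstruction.

    Returns
    -------
    times : (n,) array of culture ages in h
    densities : (n, 6) array in :data:`~ismpop.core.CLASS_COLUMNS` order
    """
    points: dict[float, tuple[float, ...]] = {}
    for rec in EVENT_DENSITY_RECORDS:
        for key, dens in (("start", rec["start_densities"]), ("end", rec["end_densities"])):
            t = rec[key]
            if t in points and points[t] != tuple(dens):
                raise ValueError(f"conflicting densities recorded at t={t}")
            points[t] = tuple(dens)
    times = np.array(sorted(points), dtype=float)
    dens = np.array([points[t] for t in times], dtype=float)
    assert dens.shape[1] == len(CLASS_COLUMNS)
    return times, dens
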
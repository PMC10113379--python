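"""Baseline-free growth-ratio estimation from periodic observations.

When the same region is photographed on two days, the two disparity maps can
be brought to a common scale by requiring the ground depth to agree: the
second map is multiplied by ``d_g(t1) / d_g'(t2)``.  The height ratio of a
plant between the epochs (its growth ratio) then reduces to disparities
alone,

    ratio = (1 - d_g'(t2) / d_p'(t2)) / (1 - d_g(t1) / d_p(t1)),

independent of both baselines — the GNSS fix only speeds up calibration, it
does not enter the ratio.  The detectable relative height change per
one-level disparity change is ``1 / (d_p - d_g)``; with a few hundred levels
across a plant this sensitivity is a fraction of a percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stereo import DisparityMap

__all__ = [
    "ObservationEpoch",
    "scale_to_common_ground",
    "growth_ratio",
    "growth_sensitivity",
    "read_epoch_registry",
]


@dataclass(frozen=True)
class ObservationEpoch:
    """Ground and plant disparity readings of one observation day."""

    epoch_id: str
    baseline: float  # metres
    ground_disparity: float  # pixels
    plant_disparity: float  # pixels

    def __post_init__(self) -> None:
        if self.ground_disparity <= 0 or self.plant_disparity <= 0:
            raise ValueError("disparities must be positive")
        if self.plant_disparity < self.ground_disparity:
            raise ValueError(
                f"plant disparity {self.plant_disparity} below ground "
                f"disparity {self.ground_disparity}"
            )


def scale_to_common_ground(
    dm_t2: DisparityMap, ground_t1: float, ground_t2: float
) -> DisparityMap:
    """Scale an epoch-2 disparity map so its ground disparity matches epoch 1."""
    if ground_t1 <= 0 or ground_t2 <= 0:
        raise ValueError("ground disparities must be positive")
    k = ground_t1 / ground_t2
    scaled = np.where(dm_t2.valid, dm_t2.disparity * k, 0.0)
    return replace(
        dm_t2,
        disparity=scaled,
        search_min=dm_t2.search_min * k,
        search_max=dm_t2.search_max * k,
    )


def growth_ratio(e1: ObservationEpoch, e2: ObservationEpoch) -> float:
    """Height ratio epoch2/epoch1 of the same plant, from disparities only."""
    if e1.plant_disparity == e1.ground_disparity:
        raise ValueError("epoch-1 plant height is zero; growth ratio undefined")
    num = 1.0 - e2.ground_disparity / e2.plant_disparity
    den = 1.0 - e1.ground_disparity / e1.plant_disparity
    return num / den


def read_epoch_registry(path: str | Path) -> list[ObservationEpoch]:
    """Read an epoch registry CSV: ``epoch_id,date,baseline_m,d_g,d_p``.

    One row per observation day; the date column is carried in the epoch id
    when present.
    """
    df = pd.read_csv(path)
    required = {"epoch_id", "baseline_m", "d_g", "d_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch registry missing columns: {sorted(missing)}")
    epochs = []
    for row in df.itertuples(index=False):
        label = str(row.epoch_id)
        if "date" in df.columns:
            label = f"{label} ({row.date})"
        epochs.append(
            ObservationEpoch(label, float(row.baseline_m), float(row.d_g), float(row.d_p))
        )
    return epochs


def growth_sensitivity(d_g: float, d_p: float) -> float:
    """Relative height change per one-level disparity change, ``1/(d_p - d_g)``."""
    if d_p <= d_g:
        raise ValueError(f"plant disparity {d_p} must exceed ground disparity {d_g}")
    return 1.0 / (d_p - d_g)
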
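"""Landmark-based centroid size and derived per-specimen size variables.

Centroid size (CS) is the standard geometric-morphometrics size measure:
the square root of the summed squared distances of a specimen's
landmarks from their centroid, multiplied by the pixel-to-mm scale. It
is invariant to translation and rotation and scales linearly with the
configuration, which makes it robust to body-shape and reproductive-
status variation compared with standard length or mass. No Procrustes
superimposition is performed: only size is analyzed, not shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from lakestream.errors import DegenerateConfigurationError, ValidationError
from lakestream.io_formats import LandmarkSet


@dataclass
class CentroidSizeResult:
    specimen_id: str
    centroid_size: float  # mm
    n_landmarks: int


def centroid_size(lm: LandmarkSet) -> CentroidSizeResult:
    """Centroid size in mm: ``scale * sqrt(sum_i ||x_i - centroid||^2)``.

    Zero iff all landmarks coincide; multiplying the coordinates (or the
    scale) by k multiplies CS by k.
    """
    coords = lm.landmarks
    if coords.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"{lm.specimen_id!r}: {coords.shape[0]} landmarks (< 3)"
        )
    if not np.all(np.isfinite(coords)):
        raise ValidationError(f"{lm.specimen_id!r}: non-finite coordinate")
    if (coords == coords[0]).all():
        return CentroidSizeResult(lm.specimen_id, 0.0, coords.shape[0])
    centered = coords - coords.mean(axis=0)
    cs = float(lm.scale * np.sqrt((centered**2).sum()))
    return CentroidSizeResult(lm.specimen_id, cs, coords.shape[0])


def centroid_sizes(sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    """Per-specimen centroid sizes as a tidy table (specimen_id, centroid_size_mm)."""
    rows = [centroid_size(lm) for lm in sets]
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in rows],
            "centroid_size_mm": [r.centroid_size for r in rows],
            "n_landmarks": [r.n_landmarks for r in rows],
        }
    )


def write_centroid_sizes(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    centroid_sizes(sets).to_csv(Path(path), sep="\t", index=False)


def egg_size(fecundity: int, clutch_dry_mass: float) -> float:
    """Average dry mass of a single egg: total clutch dry mass / egg count.

    Parameters are an egg count > 0 and the clutch dry mass in mg; the
    result is mg per egg.
    """
    if fecundity <= 0:
        raise ValidationError("egg size undefined for fecundity <= 0")
    if clutch_dry_mass < 0:
        raise ValidationError("clutch_dry_mass must be >= 0")
    return clutch_dry_mass / fecundity
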
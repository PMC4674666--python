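"""CSV readers/writers for annotations, outcomes and change scores.

Annotation CSV layout (one row per egg per phase), UTF-8, decimal point:
``nest_id, phase, egg_id, is_model_egg, blunt_x, blunt_y, sharp_x, sharp_y,
center_x, center_y, px_per_mm``.  Coordinates are image pixels (origin
top-left, y down).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import ClutchObservation, EggAnnotation

ANNOTATION_COLUMNS = [
    "nest_id", "phase", "egg_id", "is_model_egg",
    "blunt_x", "blunt_y", "sharp_x", "sharp_y",
    "center_x", "center_y", "px_per_mm",
]

CHANGE_COLUMNS = [
    "nest_id", "treatment",
    "sd_blunt_pole_distance", "sd_blunt_pole_angle",
    "sd_blunt_pole_orientation", "sd_adjacent_angle",
    "dissimilarity",
]


def annotations_to_frame(observations: list[ClutchObservation]) -> pd.DataFrame:
    rows = []
    for obs in observations:
        for egg in obs.eggs:
            rows.append(
                {
                    "nest_id": obs.nest_id,
                    "phase": obs.phase,
                    "egg_id": egg.egg_id,
                    "is_model_egg": int(egg.is_model_egg),
                    "blunt_x": egg.blunt_pole[0],
                    "blunt_y": egg.blunt_pole[1],
                    "sharp_x": egg.sharp_pole[0],
                    "sharp_y": egg.sharp_pole[1],
                    "center_x": obs.nest_center[0],
                    "center_y": obs.nest_center[1],
                    "px_per_mm": obs.px_per_mm if obs.px_per_mm is not None else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(observations: list[ClutchObservation], path) -> None:
    annotations_to_frame(observations).to_csv(path, index=False)


def frame_to_annotations(df: pd.DataFrame) -> list[ClutchObservation]:
    missing = set(ANNOTATION_COLUMNS) - {"px_per_mm"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"annotation table missing columns: {sorted(missing)}")
    observations = []
    for (nest_id, phase), grp in df.groupby(["nest_id", "phase"], sort=False):
        eggs = [
            EggAnnotation(
                egg_id=str(r.egg_id),
                blunt_pole=(float(r.blunt_x), float(r.blunt_y)),
                sharp_pole=(float(r.sharp_x), float(r.sharp_y)),
                is_model_egg=bool(int(r.is_model_egg)),
            )
            for r in grp.itertuples(index=False)
        ]
        first = grp.iloc[0]
        ppm = None
        if "px_per_mm" in grp.columns and not pd.isna(first.px_per_mm):
            ppm = float(first.px_per_mm)
        observations.append(
            ClutchObservation(
                nest_id=str(nest_id),
                phase=str(phase),
                nest_center=(float(first.center_x), float(first.center_y)),
                eggs=eggs,
                px_per_mm=ppm,
                y_down=True,
            )
        )
    return observations


def read_annotations(path) -> list[ClutchObservation]:
    return frame_to_annotations(pd.read_csv(path))


def write_change_scores(df: pd.DataFrame, path) -> None:
    cols = [c for c in CHANGE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.6f")
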
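"""Assembly of the 17-parameter phenotypic feature vector per mask.

The canonical feature order is: mask_area, Convex_Hull_Area, difference,
dif_over_mask, body_curve, perimeter, outline_curve, longest, shortest,
Hu_1…Hu_7, height.  ``dif/mask`` is spelled ``dif_over_mask`` in code and
CSV for file-system and identifier safety.

Camera height (metres) is carried as a raw calibration feature; pixel
features are never rescaled by it — the regressor learns the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import mask_io, moments, morphometry
from .errors import (
    FeatureExtractionError,
    PigmorphError,
    ValidationError,
)
from .mask_io import BinaryMask

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "extract_features",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mask_area",
    "Convex_Hull_Area",
    "difference",
    "dif_over_mask",
    "body_curve",
    "perimeter",
    "outline_curve",
    "longest",
    "shortest",
    "Hu_1",
    "Hu_2",
    "Hu_3",
    "Hu_4",
    "Hu_5",
    "Hu_6",
    "Hu_7",
    "height",
)

TABLE_COLUMNS: tuple[str, ...] = ("image_id", "animal_id", *FEATURE_NAMES, "weight_kg")


@dataclass(frozen=True)
class FeatureVector:
    mask_area: float
    Convex_Hull_Area: float
    difference: float
    dif_over_mask: float
    body_curve: float
    perimeter: float
    outline_curve: float
    longest: float
    shortest: float
    Hu_1: float
    Hu_2: float
    Hu_3: float
    Hu_4: float
    Hu_5: float
    Hu_6: float
    Hu_7: float
    height: float
    include_head_tail: bool = False  # metadata tag, not one of the 17

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}

    def values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], float)

    def __post_init__(self):
        vals = [getattr(self, name) for name in FEATURE_NAMES]
        if not np.all(np.isfinite(vals)):
            bad = [n for n, v in zip(FEATURE_NAMES, vals) if not np.isfinite(v)]
            raise ValidationError(f"non-finite feature values: {bad}")


def extract_features(
    mask: BinaryMask,
    camera_height_m: float,
    include_head_tail_mode: bool = False,
    allow_border: bool = False,
    border_margin_px: int = 0,
) -> FeatureVector:
    """Compute the canonical 17-feature vector for a single-blob mask.

    ``include_head_tail_mode`` is recorded as a metadata tag: the supplied
    mask is expected to already reflect the chosen region (body-only or full
    contour); the package does not remove heads or tails itself.

    Raises ValidationError on bad height or border-touching masks (unless
    ``allow_border``); upstream degenerate/empty errors are re-raised as
    FeatureExtractionError naming the feature that failed.
    """
    if not np.isfinite(camera_height_m) or camera_height_m <= 0:
        raise ValidationError(f"camera height must be positive, got {camera_height_m}")
    mask = mask_io.select_target_blob(mask)
    mask_io.require_nondegenerate(mask, "feature extraction")
    if not allow_border and mask_io.touches_border(mask, border_margin_px):
        raise ValidationError(
            "mask touches the image border; pass allow_border=True to override"
        )

    area = float(mask.area)

    def run(feature: str, fn):
        try:
            return fn()
        except PigmorphError as exc:
            raise FeatureExtractionError(feature, exc) from exc

    contour = run("perimeter", lambda: mask_io.trace_contour(mask))
    hull = run("Convex_Hull_Area", lambda: morphometry.convex_hull(contour, area))
    perim = run("perimeter", lambda: morphometry.perimeter(contour))
    curv = run("outline_curve", lambda: morphometry.max_contour_curvature(contour))
    axes = run(
        "longest",
        lambda: morphometry.axes_through_centroid(mask, fallback_to_nearest=True),
    )
    skel = run("body_curve", lambda: morphometry.skeleton_curve_angle(mask))
    ms = run("Hu_1", lambda: moments.compute_moments(mask))
    phi = run("Hu_1", lambda: moments.hu_invariants(ms))

    return FeatureVector(
        mask_area=area,
        Convex_Hull_Area=hull.area_px2,
        difference=hull.difference_px2,
        dif_over_mask=hull.ratio,
        body_curve=skel.body_curve_deg,
        perimeter=perim,
        outline_curve=curv.kappa_max,
        longest=axes.longest_px,
        shortest=axes.shortest_px,
        Hu_1=phi[0],
        Hu_2=phi[1],
        Hu_3=phi[2],
        Hu_4=phi[3],
        Hu_5=phi[4],
        Hu_6=phi[5],
        Hu_7=phi[6],
        height=float(camera_height_m),
        include_head_tail=include_head_tail_mode,
    )


def write_feature_table(
    records: Iterable[Sequence],
    path: str | Path,
) -> pd.DataFrame:
    """Serialize (image_id, animal_id, FeatureVector[, weight_kg]) records.

    Writes CSV with the frozen column schema; floats carry 17 significant
    digits so a read-back round-trips at that precision.  weight_kg may be
    omitted (inference mode) and is then left empty.
    """
    rows = []
    for rec in records:
        if len(rec) == 3:
            image_id, animal_id, fv = rec
            weight = np.nan
        elif len(rec) == 4:
            image_id, animal_id, fv, weight = rec
            weight = np.nan if weight is None else float(weight)
        else:
            raise ValidationError("records must be (image_id, animal_id, vector[, weight])")
        rows.append(
            {"image_id": image_id, "animal_id": animal_id, **fv.as_dict(),
             "weight_kg": weight}
        )
    if not rows:
        raise ValidationError("no records to write")
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ValidationError(f"duplicate image_id values: {dupes}")
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back, validating the frozen schema."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "weight_kg"]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    if "weight_kg" not in df.columns:
        df["weight_kg"] = np.nan
    return df[list(TABLE_COLUMNS)]
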
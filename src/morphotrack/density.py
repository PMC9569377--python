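"""Per-movie localization-density ratios between cavities and interfaces.

The spot density of a region class is the number of single-molecule
detections inside its polygons divided by the class area in rasterized
pixels.  The per-movie ratio ρc/ρi summarizes where molecules accumulate;
movies with detections missing from one class, or with only one class
annotated, are invalid and excluded from cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy

from .geometry import Region

__all__ = ["DensityRatio", "spot_density_ratio", "cohort_summary"]

#: Ratios above this are flagged for display purposes but kept in the data.
DISPLAY_CEILING = 10.0


@dataclass
class DensityRatio:
    movie_id: str
    rho_cavity: float  # detections per pixel
    rho_interface: float
    ratio: float  # rho_cavity / rho_interface
    valid: bool
    display_flagged: bool = False  # ratio above the display ceiling


def _region_area_px(regions: list[Region], label: str, pixel_pitch_um: float) -> int:
    """Class area in rasterized pixels at the mask pitch."""
    from skimage.draw import polygon as draw_polygon

    total = 0
    for r in regions:
        if r.label != label:
            continue
        coords = np.asarray(r.polygon.exterior.coords) / pixel_pitch_um
        rr, cc = draw_polygon(coords[:, 1], coords[:, 0])
        total += len(rr)
    return total


def _count_inside(detections: pd.DataFrame, regions: list[Region], label: str) -> int:
    x = detections["x_um"].to_numpy()
    y = detections["y_um"].to_numpy()
    inside = np.zeros(len(x), dtype=bool)
    for r in regions:
        if r.label != label:
            continue
        # boundary-inclusive point-in-polygon
        inside |= contains_xy(r.polygon, x, y) | contains_xy(
            r.polygon.boundary, x, y
        )
    return int(inside.sum())


def spot_density_ratio(
    detections,
    regions: list[Region],
    movie_id: str = "",
    pixel_pitch_um: float = 0.166,
) -> DensityRatio:
    """Cavity-to-interface spot density ratio for one movie.

    Areas are measured in rasterized pixels at ``pixel_pitch_um``.  The
    result is invalid when only one region class is annotated or when one
    class records no detections; ratios above 10 are display-flagged but
    retained.
    """
    df = pd.DataFrame(detections)
    labels = {r.label for r in regions}
    if labels != {"interface", "cavity"}:
        return DensityRatio(movie_id, np.nan, np.nan, np.nan, valid=False)
    area_c = _region_area_px(regions, "cavity", pixel_pitch_um)
    area_i = _region_area_px(regions, "interface", pixel_pitch_um)
    if area_c == 0 or area_i == 0:
        raise ValueError("zero-area region class")
    n_c = _count_inside(df, regions, "cavity")
    n_i = _count_inside(df, regions, "interface")
    if n_c == 0 or n_i == 0:
        return DensityRatio(
            movie_id, n_c / area_c, n_i / area_i, np.nan, valid=False
        )
    rho_c = n_c / area_c
    rho_i = n_i / area_i
    ratio = rho_c / rho_i
    return DensityRatio(
        movie_id,
        rho_c,
        rho_i,
        float(ratio),
        valid=True,
        display_flagged=ratio > DISPLAY_CEILING,
    )


def cohort_summary(ratios_by_condition: dict[str, list[DensityRatio]]) -> pd.DataFrame:
    """Median and quartiles of valid ratios per condition.

    Invalid movies are excluded; an empty condition raises.  Group
    comparison statistics are deliberately not computed here.
    """
    rows = []
    for condition, ratios in ratios_by_condition.items():
        values = np.asarray([r.ratio for r in ratios if r.valid])
        if values.size == 0:
            raise ValueError(f"condition {condition!r} has no valid ratios")
        rows.append(
            {
                "condition": condition,
                "n_movies": values.size,
                "median": float(np.median(values)),
                "q25": float(np.quantile(values, 0.25)),
                "q75": float(np.quantile(values, 0.75)),
            }
        )
    return pd.DataFrame(rows)
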
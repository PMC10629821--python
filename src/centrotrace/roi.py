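"""Ventricle-centred region-of-interest geometry.

Reproduces the manual analysis construction used on cortical-unit images:

* an analysis circle centred on the ventricle midpoint with radius
  ``min(3 * vz_thickness, tissue_radius)``;
* removal of the ventricle interior (keeping the ring of wall centrosomes,
  never discarding recombined cluster members);
* a wedge over a recombined cluster, bounded by the chord between the two
  cluster ends, two rays leaving the chord ends at 45 degrees opening
  outward, and the arc of the analysis circle — the radial line through the
  chord midpoint is used only to orient "outward";
* assignment of each centrosome to the ventricular wall (VENT), the analysed
  surround (NONVENT) or EXCLUDED.

All predicates are pure vector geometry, hence invariant under uniform
scaling of coordinates and annotation lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ParameterError
from .layout import CorticalUnitAnnotation

__all__ = [
    "RegionLabel",
    "WedgeROI",
    "analysis_circle",
    "crop_ventricle_interior",
    "build_wedge",
    "assign_region",
]


class RegionLabel(str, Enum):
    VENT = "VENT"
    NONVENT = "NONVENT"
    EXCLUDED = "EXCLUDED"


def analysis_circle(annotation: CorticalUnitAnnotation) -> tuple[tuple[float, float], float]:
    """Circle bounding the analysed area of one cortical unit.

    Centred on the ventricle midpoint; radius is three VZ thicknesses or the
    tissue radius, whichever is smaller.
    """
    if annotation.vz_thickness <= 0:
        raise ParameterError("vz_thickness must be positive")
    return annotation.centre, min(3.0 * annotation.vz_thickness, annotation.tissue_radius)


def crop_ventricle_interior(
    centrosomes: pd.DataFrame,
    annotation: CorticalUnitAnnotation,
    delta: float = 2.0,
    protect_recombined: bool = True,
) -> pd.DataFrame:
    """Drop centrosomes inside the ventricle lumen.

    Removes rows with radial distance below ``lumen_radius - delta``, except
    (by default) recombined centrosomes, mirroring the care taken not to crop
    recombined cluster members during manual analysis.
    """
    cx, cy = annotation.centre
    r = np.hypot(centrosomes["x"] - cx, centrosomes["y"] - cy)
    interior = r < annotation.lumen_radius - delta
    if protect_recombined and "recombined" in centrosomes:
        interior &= ~centrosomes["recombined"].astype(bool)
    return centrosomes.loc[~interior]


@dataclass(frozen=True)
class WedgeROI:
    """Wedge over a recombined cluster.

    ``chord_endpoints`` are the two ends of the cluster; the membership region
    lies on the outward side of the chord, between the two 45-degree rays,
    inside the analysis circle.
    """

    chord_endpoints: tuple[tuple[float, float], tuple[float, float]]
    circle_centre: tuple[float, float]
    circle_radius: float
    ray_angle_deg: float = 45.0

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-membership predicate (boundary inclusive)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p1 = np.asarray(self.chord_endpoints[0], dtype=float)
        p2 = np.asarray(self.chord_endpoints[1], dtype=float)
        c = np.asarray(self.circle_centre, dtype=float)
        u = p2 - p1
        u = u / np.hypot(*u)
        # outward normal: away from the circle centre, oriented by the
        # radial line through the chord midpoint
        n = np.array([-u[1], u[0]])
        mid = 0.5 * (p1 + p2)
        if abs(float(np.dot(n, mid - c))) < 1e-12:
            raise ParameterError("chord passes through the circle centre; outward side undefined")
        if np.dot(n, mid - c) < 0:
            n = -n
        ang = np.deg2rad(self.ray_angle_deg)
        d1 = -u * np.cos(ang) + n * np.sin(ang)  # ray leaving p1
        d2 = u * np.cos(ang) + n * np.sin(ang)  # ray leaving p2
        qx, qy = x - p1[0], y - p1[1]
        outward = qx * n[0] + qy * n[1] >= 0.0
        # inside means on the same side of each ray line as the opposite endpoint
        s1 = d1[0] * qy - d1[1] * qx
        s1_ref = d1[0] * (p2[1] - p1[1]) - d1[1] * (p2[0] - p1[0])
        rx, ry = x - p2[0], y - p2[1]
        s2 = d2[0] * ry - d2[1] * rx
        s2_ref = d2[0] * (p1[1] - p2[1]) - d2[1] * (p1[0] - p2[0])
        between = (s1 * np.sign(s1_ref) >= 0.0) & (s2 * np.sign(s2_ref) >= 0.0)
        in_circle = (x - c[0]) ** 2 + (y - c[1]) ** 2 <= self.circle_radius**2
        return outward & between & in_circle


def build_wedge(
    cluster_endpoints: tuple[tuple[float, float], tuple[float, float]],
    circle_centre: tuple[float, float],
    circle_radius: float,
) -> WedgeROI:
    """Construct the 45-degree wedge over a recombined cluster."""
    p1 = np.asarray(cluster_endpoints[0], dtype=float)
    p2 = np.asarray(cluster_endpoints[1], dtype=float)
    if np.allclose(p1, p2):
        raise ParameterError("cluster endpoints must be distinct")
    c = np.asarray(circle_centre, dtype=float)
    for p in (p1, p2):
        if np.hypot(*(p - c)) > circle_radius:
            raise ParameterError(f"endpoint {tuple(p)} lies outside the analysis circle")
    wedge = WedgeROI(
        chord_endpoints=(tuple(p1), tuple(p2)),
        circle_centre=tuple(c),
        circle_radius=float(circle_radius),
    )
    wedge.contains(*wedge.circle_centre)  # validates orientation is defined
    return wedge


def assign_region(
    x,
    y,
    annotation: CorticalUnitAnnotation,
    wedge: WedgeROI | None = None,
    wall_tolerance: float | None = None,
) -> np.ndarray:
    """Label positions VENT / NONVENT / EXCLUDED.

    A centrosome is VENT when its radial distance is within ``wall_tolerance``
    (default half the VZ thickness — the manual criterion is visual, so the
    band is configurable) of the lumen radius.  Otherwise it is NONVENT when
    inside the wedge (if one is supplied) or inside the analysis circle, and
    EXCLUDED beyond that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if wall_tolerance is None:
        wall_tolerance = 0.5 * annotation.vz_thickness
    (cx, cy), radius = analysis_circle(annotation)
    r = np.hypot(x - cx, y - cy)
    vent = np.abs(r - annotation.lumen_radius) <= wall_tolerance
    if wedge is not None:
        analysed = wedge.contains(x, y)
    else:
        analysed = r <= radius
    labels = np.where(vent, RegionLabel.VENT.value,
                      np.where(analysed, RegionLabel.NONVENT.value, RegionLabel.EXCLUDED.value))
    return labels
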
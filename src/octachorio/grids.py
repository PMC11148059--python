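"""Sector grids for regional OCTA analysis.

Two layouts are provided:

* a macular nine-zone grid: a central 1-mm-diameter fovea disc, a 1–3 mm
  parafoveal annulus and a 3–6 mm perifoveal annulus, each annulus split into
  superior / inferior / nasal / temporal quadrants by the two 45° diagonals
  through the fovea (the classic X-shaped ETDRS division);
* a peripapillary nine-zone grid: the optic-disc circle plus a 2-mm-wide
  annulus measured radially outward from the disc boundary, split into eight
  45° sectors whose boundaries lie on the vertical and horizontal axes.

Laterality convention: for a right eye (OD) the nasal side is the image
right (+col direction); for a left eye (OS) the grid is mirrored across the
vertical axis so nasal is on the image left.  Pixel membership uses the
pixel-centre distance from the grid centre, 0-based ``(row, col)``
coordinates, and half-open angular intervals ``[lo, hi)`` so every pixel
belongs to exactly one sector.
"""

from __future__ import annotations

import numpy as np

from ._containers import SectorGrid

__all__ = [
    "MACULAR_ZONES",
    "PERIPAPILLARY_ZONES",
    "build_macular_grid",
    "build_peripapillary_grid",
    "regional_mean",
]

MACULAR_ZONES: tuple[str, ...] = (
    "fovea", "2I", "2T", "2S", "2N", "3I", "3T", "3S", "3N",
)

#: Eight 45° ring sectors named <hemifield><half>: e.g. NS = nasal hemifield,
#: superior half; SN = superior hemifield, nasal half.
PERIPAPILLARY_ZONES: tuple[str, ...] = (
    "inside_disc", "NS", "NI", "IN", "IT", "TI", "TS", "ST", "SN",
)


def _polar(image_shape: tuple[int, int], center_px: tuple[float, float],
           laterality: str) -> tuple[np.ndarray, np.ndarray]:
    """Radius (px) and angle (deg in [0, 360)) maps about ``center_px``.

    Angle 0 points toward the nasal side, 90° is superior (up), measured
    counter-clockwise in the (nasal-right, up) frame.  For OS the horizontal
    axis is mirrored so 0° is again nasal.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    rows, cols = np.indices(image_shape, dtype=float)
    dy = -(rows - center_px[0])           # up is positive
    dx = cols - center_px[1]              # image right is positive
    if laterality == "OS":
        dx = -dx                          # nasal on the image left
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(dy, dx)) % 360.0
    return radius, angle


def build_macular_grid(center_px: tuple[float, float], image_shape: tuple[int, int],
                       scale_um_per_px: float, laterality: str = "OD",
                       diameters_mm: tuple[float, float, float] = (1.0, 3.0, 6.0),
                       ) -> SectorGrid:
    """Build the nine-zone macular grid centred on the fovea.

    Raises ``ValueError`` if the outer circle does not fit inside the image.
    """
    r_fovea, r_para, r_peri = (d * 1000.0 / 2.0 / scale_um_per_px for d in diameters_mm)
    h, w = image_shape
    cy, cx = center_px
    # the outermost pixel extends 0.5 px beyond its centre
    if min(cy, cx, h - 1 - cy, w - 1 - cx) + 0.5 < r_peri:
        raise ValueError(
            f"{diameters_mm[2]}-mm circle (radius {r_peri:.1f} px) exceeds image bounds"
        )

    radius, angle = _polar(image_shape, center_px, laterality)
    labels = np.zeros(image_shape, dtype=np.int32)

    # Quadrants split by the 45° diagonals; angle 0 = nasal, 90 = superior.
    quad = np.full(image_shape, -1, dtype=np.int8)
    shifted = (angle + 45.0) % 360.0  # nasal quadrant becomes [0, 90)
    quad[(shifted >= 0) & (shifted < 90)] = 0    # N
    quad[(shifted >= 90) & (shifted < 180)] = 1  # S
    quad[(shifted >= 180) & (shifted < 270)] = 2  # T
    quad[shifted >= 270] = 3                      # I

    labels[radius < r_fovea] = 1  # fovea
    para = (radius >= r_fovea) & (radius < r_para)
    peri = (radius >= r_para) & (radius < r_peri)
    quad_to_zone = {3: "I", 2: "T", 1: "S", 0: "N"}
    for q, suffix in quad_to_zone.items():
        labels[para & (quad == q)] = MACULAR_ZONES.index("2" + suffix) + 1
        labels[peri & (quad == q)] = MACULAR_ZONES.index("3" + suffix) + 1

    return SectorGrid(labels=labels, zone_names=MACULAR_ZONES,
                      scale_um_per_px=scale_um_per_px, center_px=tuple(center_px),
                      laterality=laterality, kind="macula")


def build_peripapillary_grid(disc_center_px: tuple[float, float],
                             image_shape: tuple[int, int], scale_um_per_px: float,
                             laterality: str = "OD", disc_radius_um: float = 750.0,
                             ring_width_um: float = 2000.0) -> SectorGrid:
    """Build the nine-zone peripapillary grid centred on the optic disc.

    The measurement annulus extends ``ring_width_um`` radially outward from
    the disc boundary.  The disc radius is a free parameter (default 750 µm).
    """
    r_disc = disc_radius_um / scale_um_per_px
    r_outer = (disc_radius_um + ring_width_um) / scale_um_per_px
    h, w = image_shape
    cy, cx = disc_center_px
    if min(cy, cx, h - 1 - cy, w - 1 - cx) + 0.5 < r_outer:
        raise ValueError("peripapillary ring exceeds image bounds")

    radius, angle = _polar(image_shape, disc_center_px, laterality)
    labels = np.zeros(image_shape, dtype=np.int32)
    labels[radius < r_disc] = 1  # inside_disc

    # 45° sectors with boundaries on the axes; angle 0 = nasal, CCW toward
    # superior.  Sector k covers [45k, 45(k+1)).
    sector_names = ("NS", "SN", "ST", "TS", "TI", "IT", "IN", "NI")
    ring = (radius >= r_disc) & (radius < r_outer)
    sector = np.floor_divide(angle, 45.0).astype(int) % 8
    for k, name in enumerate(sector_names):
        labels[ring & (sector == k)] = PERIPAPILLARY_ZONES.index(name) + 1

    return SectorGrid(labels=labels, zone_names=PERIPAPILLARY_ZONES,
                      scale_um_per_px=scale_um_per_px, center_px=tuple(disc_center_px),
                      laterality=laterality, kind="peripapillary")


def regional_mean(metric_map: np.ndarray, grid: SectorGrid,
                  ) -> tuple[dict[str, float], tuple[str, ...]]:
    """Arithmetic mean of ``metric_map`` over every grid zone.

    Returns ``(means, missing)`` where zones without any labelled pixel carry
    NaN in ``means`` and are listed in ``missing``.  NaN pixels in the metric
    map are ignored (useful for maps defined only on part of the field).
    """
    metric_map = np.asarray(metric_map, dtype=float)
    if metric_map.shape != grid.labels.shape:
        raise ValueError(
            f"metric map shape {metric_map.shape} != grid shape {grid.labels.shape}"
        )
    means: dict[str, float] = {}
    missing: list[str] = []
    for i, name in enumerate(grid.zone_names):
        values = metric_map[grid.labels == i + 1]
        values = values[~np.isnan(values)]
        if values.size == 0:
            means[name] = float("nan")
            missing.append(name)
        else:
            means[name] = float(values.mean())
    return means, tuple(missing)
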
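"""Per-zone vessel density for en face slabs (SCP / DCP / RPC / CC).

Vessel density is the percentage of a zone's pixels classified as vessel
after binarisation.  Device software keeps its binarisation proprietary, so
the default here is the parameter-free global Otsu threshold, with a
fixed-threshold alternative; the method used is recorded in the result.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from ._containers import EnFaceImage, SectorGrid, VesselDensityResult

__all__ = ["binarize_slab", "vessel_density_regional"]


def binarize_slab(slab: EnFaceImage, method: str = "otsu",
                  threshold: float = 0.5) -> np.ndarray:
    """Binarise a normalised en face slab; vessel pixels become True.

    ``method="otsu"`` uses the global Otsu threshold (error on a constant
    image); ``method="fixed"`` uses ``threshold`` with pixels ≥ threshold as
    vessel.
    """
    data = slab.data
    if data.min() < 0 or data.max() > 1:
        raise ValueError("slab must be normalised to [0, 1]")
    if method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError("constant image: Otsu threshold undefined")
        return data >= threshold_otsu(data)
    if method == "fixed":
        return data >= threshold
    raise ValueError(f"unknown binarisation method {method!r}")


def vessel_density_regional(mask: np.ndarray, grid: SectorGrid,
                            slab: str = "SCP",
                            method: str = "otsu") -> VesselDensityResult:
    """Vessel density (%) of ``mask`` over every grid zone."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.labels.shape:
        raise ValueError("mask and grid shapes differ")
    density: dict[str, float] = {}
    missing: list[str] = []
    for i, name in enumerate(grid.zone_names):
        sel = grid.labels == i + 1
        n = int(sel.sum())
        if n == 0:
            density[name] = float("nan")
            missing.append(name)
        else:
            density[name] = 100.0 * float(mask[sel].sum()) / n
    return VesselDensityResult(slab=slab, density_pct=density,
                               missing_zones=tuple(missing), method=method)
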
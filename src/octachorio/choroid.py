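"""Choroidal thickness (CT) and choroidal vascularity index (CVI).

CT is the distance between Bruch's membrane and the choroid–sclera
interface; CVI is the luminal fraction of the choroid band.  Both are
computed from boundary-annotated B-scan stacks: the traces give the band,
Niblack local thresholding inside the band separates dark vascular lumina
from bright stroma (the binarisation standard in the CVI literature), and
pixels are pooled per macular-grid zone.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_niblack

from ._containers import ChoroidBScanStack, ChoroidRegionalResult, SectorGrid
from .grids import regional_mean

__all__ = [
    "thickness_map",
    "binarize_choroid_lumen",
    "cvi_ct_regional",
    "resample_grid_labels",
    "NIBLACK_WINDOW",
    "NIBLACK_K",
]

NIBLACK_WINDOW = 51
NIBLACK_K = -0.05


def thickness_map(stack: ChoroidBScanStack) -> np.ndarray:
    """Per-A-scan choroidal thickness in µm, shape ``(n_bscans, n_ascans)``.

    Depends only on the boundary traces, never on the image content.  Raises
    ``ValueError`` naming the first offending A-scan if the traces cross.
    """
    diff = stack.csi_trace - stack.bruch_trace
    if (diff < 0).any():
        b, a = np.argwhere(diff < 0)[0]
        raise ValueError(
            f"choroid-sclera interface above Bruch's membrane at B-scan {b}, A-scan {a}"
        )
    return diff.astype(float) * stack.axial_um_per_px


def binarize_choroid_lumen(stack: ChoroidBScanStack, *,
                           window: int = NIBLACK_WINDOW,
                           k: float = NIBLACK_K) -> np.ndarray:
    """Niblack binarisation of the choroid band: dark pixels become lumen.

    The threshold surface ``T = m - k·s`` (local mean and SD over a
    ``window``-pixel square) is computed on each full B-scan; the lumen mask
    is ``intensity < T`` restricted to the band between the traces.
    """
    band = stack.band_mask()
    if not band.any():
        raise ValueError("empty choroid band: traces coincide everywhere")
    lumen = np.zeros_like(band)
    for b in range(stack.n_bscans):
        t = threshold_niblack(stack.bscans[b], window_size=window, k=k)
        # the epsilon keeps a perfectly uniform window from classifying
        # itself as lumen through convolution round-off (~1e-8)
        lumen[b] = (stack.bscans[b] < t - 1e-6) & band[b]
    return lumen


def resample_grid_labels(grid: SectorGrid, n_bscans: int, n_ascans: int) -> np.ndarray:
    """Nearest-neighbour resampling of the grid label map to the stack raster.

    B-scans are assumed to be evenly spaced rows of the en face field the
    grid was built for; A-scans evenly spaced columns.
    """
    h, w = grid.labels.shape
    rows = np.rint(np.linspace(0, h - 1, n_bscans)).astype(int)
    cols = np.rint(np.linspace(0, w - 1, n_ascans)).astype(int)
    return grid.labels[np.ix_(rows, cols)]


def cvi_ct_regional(stack: ChoroidBScanStack, grid: SectorGrid, *,
                    window: int = NIBLACK_WINDOW, k: float = NIBLACK_K,
                    ) -> ChoroidRegionalResult:
    """Per-zone CT (µm) and CVI over a macular grid.

    CVI pools pixels across all A-scans of a zone: luminal pixel count over
    choroid-band pixel count.  When the stack carries a ground-truth
    ``luminal_mask`` the Niblack step is skipped.  Zones with no A-scans (or
    an empty band) are flagged missing and carry NaN.
    """
    if grid.kind != "macula":
        raise ValueError("cvi_ct_regional expects a macular grid")
    thick = thickness_map(stack)
    if stack.luminal_mask is not None:
        lumen = np.asarray(stack.luminal_mask, dtype=bool)
        if lumen.shape != stack.bscans.shape:
            raise ValueError("luminal mask shape mismatch")
        lumen = lumen & stack.band_mask()
    else:
        lumen = binarize_choroid_lumen(stack, window=window, k=k)
    band = stack.band_mask()

    labels = resample_grid_labels(grid, stack.n_bscans, stack.n_ascans)
    ct_means, ct_missing = regional_mean(thick, _GridView(labels, grid))

    cvi: dict[str, float] = {}
    missing = set(ct_missing)
    lumen_cols = lumen.sum(axis=1)  # (n_bscans, n_ascans)
    band_cols = band.sum(axis=1)
    for i, name in enumerate(grid.zone_names):
        sel = labels == i + 1
        total = int(band_cols[sel].sum())
        if total == 0:
            cvi[name] = float("nan")
            missing.add(name)
        else:
            cvi[name] = float(lumen_cols[sel].sum()) / total
    return ChoroidRegionalResult(ct_um=ct_means, cvi=cvi,
                                 missing_zones=tuple(sorted(missing)))


class _GridView:
    """Light stand-in exposing a resampled label map to :func:`regional_mean`."""

    def __init__(self, labels: np.ndarray, grid: SectorGrid):
        self.labels = labels
        self.zone_names = grid.zone_names
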
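"""Choriocapillaris flow-deficit (CC FD) quantification.

The pipeline mirrors the standard en face CC analysis chain:

1. a large-vessel projection mask is obtained from the retinal composite
   slab by fixed-threshold binarisation and used to exclude shadowed pixels;
2. fuzzy C-means (FCM) clustering of the remaining CC intensities separates
   flowing choriocapillaris from flow deficits (the darkest cluster);
3. connected components with an equivalent diameter below 24 µm — the
   nominal intercapillary distance — are discarded (components *at* the
   cutoff are retained);
4. the surviving components are summarised as mean FD size (µm²) and FD
   density (% of the analysed area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from ._containers import CCFDMetrics, EnFaceImage, FlowDeficitSet, VesselMask

__all__ = [
    "binarize_large_vessels",
    "fcm_segment",
    "FCMResult",
    "label_and_filter",
    "ccfd_metrics",
    "quantify_ccfd",
    "DEFAULT_VESSEL_THRESHOLD",
    "DEFAULT_MIN_EQUIV_DIAMETER_UM",
]

DEFAULT_VESSEL_THRESHOLD = 0.6
DEFAULT_MIN_EQUIV_DIAMETER_UM = 24.0

#: absolute slop on the equivalent-diameter cutoff so that a component whose
#: diameter equals the cutoff exactly survives floating-point rasterisation
_DIAMETER_TOL_UM = 1e-9


def binarize_large_vessels(retina: EnFaceImage,
                           threshold: float = DEFAULT_VESSEL_THRESHOLD) -> VesselMask:
    """Fixed-threshold binarisation of the retinal slab: pixels ≥ threshold.

    The input must be normalised to [0, 1]; anything outside is rejected so a
    raw 8/16-bit image cannot silently produce an empty or full mask.
    """
    data = retina.data
    if data.min() < 0 or data.max() > 1:
        raise ValueError("retina image must be normalised to [0, 1]")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return VesselMask(mask=data >= threshold, threshold=float(threshold))


@dataclass
class FCMResult:
    """Outcome of :func:`fcm_segment`.

    ``fd_map`` is the binary flow-deficit map (darkest cluster, excluded
    pixels forced to False).  ``membership`` has shape ``(n_included,
    n_clusters)`` and rows summing to 1, aligned with ``included_indices``
    (flat indices into the image).
    """

    fd_map: np.ndarray
    centroids: np.ndarray
    membership: np.ndarray
    included_indices: np.ndarray
    n_iter: int
    converged: bool


def _fcm_1d(values: np.ndarray, centroids: np.ndarray, m: float, tol: float,
            max_iter: int) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Vectorised fuzzy C-means on scalar intensities.

    Alternates the closed-form updates: memberships
    ``u_ik ∝ d_ik^(-2/(m-1))`` normalised over clusters, centroids as
    ``u^m``-weighted means.  Stops when the largest centroid shift falls
    below ``tol``.
    """
    exponent = 2.0 / (m - 1.0)
    converged = False
    u = np.empty((values.size, centroids.size))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = np.abs(values[:, None] - centroids[None, :])
        # exact hits: full membership on the coincident centroid(s)
        zero = dist < 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            inv = dist ** (-exponent)
            u = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        um = u**m
        new_centroids = (um * values[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    return centroids, u, n_iter, converged


def fcm_segment(cc: EnFaceImage, exclude: VesselMask | None = None, *,
                clusters: int = 2, fuzziness_m: float = 2.0, tol: float = 1e-5,
                max_iter: int = 300, init: str = "percentile",
                seed: int | None = None) -> FCMResult:
    """Segment flow deficits from a CC en face image by fuzzy C-means.

    Pixels under the large-vessel mask are excluded from the clustering
    objective and forced to background in the returned FD map.  Cluster
    centroids are initialised deterministically at evenly spaced intensity
    percentiles between the 10th and 90th (``init="percentile"``); random
    initialisation (``init="random"``) draws from the included intensities
    and is the only use of ``seed``.

    Raises ``ValueError`` when the included intensities are constant (the
    objective is degenerate) or when no pixel survives the exclusion mask.
    """
    if clusters < 2:
        raise ValueError("clusters must be >= 2")
    if fuzziness_m <= 1:
        raise ValueError("fuzziness_m must be > 1")
    data = cc.data
    if exclude is not None:
        if exclude.shape != data.shape:
            raise ValueError("exclusion mask shape mismatch")
        include = ~exclude.mask
    else:
        include = np.ones(data.shape, dtype=bool)
    flat_idx = np.flatnonzero(include)
    if flat_idx.size == 0:
        raise ValueError("no pixels left after vessel exclusion")
    values = data.ravel()[flat_idx].astype(float)
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: included intensities are constant")

    if init == "percentile":
        qs = np.linspace(10, 90, clusters)
        centroids = np.percentile(values, qs)
        # coincident percentiles would collapse clusters; nudge apart
        for k in range(1, clusters):
            if centroids[k] <= centroids[k - 1]:
                centroids[k] = centroids[k - 1] + 1e-6
    elif init == "random":
        rng = np.random.default_rng(seed)
        centroids = rng.choice(values, size=clusters, replace=False)
        centroids.sort()
    else:
        raise ValueError(f"unknown init {init!r}")

    centroids, u, n_iter, converged = _fcm_1d(values, centroids, fuzziness_m,
                                              tol, max_iter)
    hard = np.argmax(u, axis=1)
    darkest = int(np.argmin(centroids))
    fd_map = np.zeros(data.shape, dtype=bool)
    fd_map.ravel()[flat_idx[hard == darkest]] = True
    return FCMResult(fd_map=fd_map, centroids=centroids, membership=u,
                     included_indices=flat_idx, n_iter=n_iter, converged=converged)


def label_and_filter(fd_map: np.ndarray, exclude: VesselMask | None,
                     scale_um_per_px: float,
                     min_equiv_diameter_um: float = DEFAULT_MIN_EQUIV_DIAMETER_UM,
                     ) -> FlowDeficitSet:
    """Label FD components (8-connectivity) and drop the sub-resolution ones.

    A component's equivalent diameter is ``2·sqrt(area/π)`` with the area in
    µm² from its pixel count.  Components *smaller than* the cutoff are
    excluded; a diameter equal to the cutoff is retained.  The analysed area
    is the field area minus the excluded vessel-projection area.
    """
    fd_map = np.asarray(fd_map, dtype=bool)
    if exclude is not None:
        if exclude.shape != fd_map.shape:
            raise ValueError("exclusion mask shape mismatch")
        fd_map = fd_map & ~exclude.mask
        excluded_px = int(exclude.mask.sum())
    else:
        excluded_px = 0
    px_area_um2 = scale_um_per_px**2
    labels = measure.label(fd_map, connectivity=2)
    counts = np.bincount(labels.ravel())
    areas = counts[1:] * px_area_um2
    diameters = 2.0 * np.sqrt(areas / np.pi)
    keep = diameters >= min_equiv_diameter_um - _DIAMETER_TOL_UM

    # relabel retained components consecutively, drop the rest
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    label_map = remap[labels]
    analyzed = (fd_map.size - excluded_px) * px_area_um2
    return FlowDeficitSet(label_map=label_map, areas_um2=areas[keep],
                          equivalent_diameters_um=diameters[keep],
                          analyzed_area_um2=float(analyzed),
                          scale_um_per_px=scale_um_per_px,
                          min_equiv_diameter_um=min_equiv_diameter_um)


def ccfd_metrics(fds: FlowDeficitSet) -> CCFDMetrics:
    """Mean FD size (µm²) and FD density (% of the analysed area).

    With zero retained components the mean size is NaN (not computable) and
    the density is 0.
    """
    if fds.analyzed_area_um2 <= 0:
        raise ValueError("analysed area must be positive")
    total = float(fds.areas_um2.sum())
    if fds.count == 0:
        return CCFDMetrics(mean_fd_size_um2=float("nan"), fd_density_pct=0.0,
                           fd_count=0, analyzed_area_um2=fds.analyzed_area_um2)
    return CCFDMetrics(mean_fd_size_um2=total / fds.count,
                       fd_density_pct=100.0 * total / fds.analyzed_area_um2,
                       fd_count=fds.count,
                       analyzed_area_um2=fds.analyzed_area_um2)


def quantify_ccfd(cc: EnFaceImage, retina: EnFaceImage | None = None, *,
                  vessel_threshold: float = DEFAULT_VESSEL_THRESHOLD,
                  min_equiv_diameter_um: float = DEFAULT_MIN_EQUIV_DIAMETER_UM,
                  **fcm_kwargs) -> tuple[CCFDMetrics, FlowDeficitSet, VesselMask | None]:
    """Convenience wrapper running the full CC FD chain on one image pair."""
    mask = binarize_large_vessels(retina, vessel_threshold) if retina is not None else None
    seg = fcm_segment(cc, mask, **fcm_kwargs)
    fds = label_and_filter(seg.fd_map, mask, cc.scale_um_per_px, min_equiv_diameter_um)
    return ccfd_metrics(fds), fds, mask
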
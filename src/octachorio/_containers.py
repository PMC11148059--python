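"""Core in-memory containers shared across the quantification modules.

Conventions used throughout the package:

* images are 2-D ``float`` arrays with intensities normalised to ``[0, 1]``,
  indexed ``(row, col)`` with 0-based pixel coordinates;
* lateral scales are in µm per pixel, axial scales in µm per pixel;
* areas are reported in µm², thicknesses in µm, densities in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnFaceImage",
    "SectorGrid",
    "VesselMask",
    "FlowDeficitSet",
    "CCFDMetrics",
    "ChoroidBScanStack",
    "ChoroidRegionalResult",
    "VesselDensityResult",
]


@dataclass
class EnFaceImage:
    """A 2-D en face OCTA slab projection.

    Parameters
    ----------
    data
        Grayscale intensities in ``[0, 1]``, shape ``(rows, cols)``.
    scale_um_per_px
        Lateral sampling, identical in both directions (square pixels).
    modality
        Slab tag, e.g. ``"CC"``, ``"retina"``, ``"SCP"``.
    center_px
        Anatomical centre (fovea or disc) as ``(row, col)``; defaults to the
        geometric image centre.
    """

    data: np.ndarray
    scale_um_per_px: float
    modality: str = "unknown"
    center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("en face image must be 2-D")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.center_px is None:
            self.center_px = ((self.data.shape[0] - 1) / 2.0, (self.data.shape[1] - 1) / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def field_area_um2(self) -> float:
        return float(self.data.size) * self.scale_um_per_px**2


@dataclass
class SectorGrid:
    """Labelled sector mask: each pixel carries an integer zone code.

    Zone code 0 is background (outside every sector); codes ``1..n`` map to
    ``zone_names[code - 1]``.
    """

    labels: np.ndarray
    zone_names: tuple[str, ...]
    scale_um_per_px: float
    center_px: tuple[float, float]
    laterality: str
    kind: str  # "macula" or "peripapillary"

    def zone_code(self, name: str) -> int:
        return self.zone_names.index(name) + 1

    def zone_mask(self, name: str) -> np.ndarray:
        return self.labels == self.zone_code(name)

    def pixel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.zone_names) + 1)
        return {name: int(counts[i + 1]) for i, name in enumerate(self.zone_names)}

    def zone_area_um2(self, name: str) -> float:
        return self.pixel_counts()[name] * self.scale_um_per_px**2


@dataclass
class VesselMask:
    """Binary large-vessel projection mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class FlowDeficitSet:
    """Connected flow-deficit components surviving the size filter.

    ``label_map`` holds consecutive labels ``1..n`` for retained components;
    ``areas_um2[i]`` and ``equivalent_diameters_um[i]`` describe label
    ``i + 1``.  ``analyzed_area_um2`` is the field area minus the excluded
    large-vessel projection area.
    """

    label_map: np.ndarray
    areas_um2: np.ndarray
    equivalent_diameters_um: np.ndarray
    analyzed_area_um2: float
    scale_um_per_px: float
    min_equiv_diameter_um: float

    @property
    def count(self) -> int:
        return int(self.areas_um2.size)


@dataclass
class CCFDMetrics:
    """Summary flow-deficit indices for one CC en face image."""

    mean_fd_size_um2: float  # NaN when no FD was detected
    fd_density_pct: float
    fd_count: int
    analyzed_area_um2: float


@dataclass
class ChoroidBScanStack:
    """Choroid B-scan stack with boundary traces.

    Attributes
    ----------
    bscans
        Intensities, shape ``(n_bscans, n_rows, n_ascans)``, in ``[0, 1]``.
    bruch_trace, csi_trace
        Row index of Bruch's membrane and of the choroid–sclera interface for
        every A-scan, shape ``(n_bscans, n_ascans)``.  The choroid band at
        A-scan ``(b, a)`` occupies rows ``bruch[b, a] .. csi[b, a] - 1``
        (half-open), so band height in pixels equals ``csi - bruch``.
    luminal_mask
        Optional ground-truth luminal mask aligned with ``bscans``; when
        present the Niblack binarisation is skipped by the CVI computation.
    """

    bscans: np.ndarray
    bruch_trace: np.ndarray
    csi_trace: np.ndarray
    axial_um_per_px: float
    lateral_um_per_px: float
    bscan_spacing_um: float
    luminal_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans, dtype=float)
        self.bruch_trace = np.asarray(self.bruch_trace, dtype=int)
        self.csi_trace = np.asarray(self.csi_trace, dtype=int)
        if self.bscans.ndim != 3:
            raise ValueError("bscans must have shape (n_bscans, n_rows, n_ascans)")
        if self.bruch_trace.shape != self.csi_trace.shape:
            raise ValueError("trace shapes differ")
        expected = (self.bscans.shape[0], self.bscans.shape[2])
        if self.bruch_trace.shape != expected:
            raise ValueError(f"traces must have shape {expected}")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.bscans.shape[2]

    def band_mask(self) -> np.ndarray:
        """Boolean mask of the choroid band, aligned with ``bscans``."""
        rows = np.arange(self.bscans.shape[1])[None, :, None]
        return (rows >= self.bruch_trace[:, None, :]) & (rows < self.csi_trace[:, None, :])


@dataclass
class ChoroidRegionalResult:
    """Per-zone choroidal thickness (µm) and vascularity index."""

    ct_um: dict[str, float]
    cvi: dict[str, float]
    missing_zones: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class VesselDensityResult:
    """Per-zone vessel density (%) for one slab."""

    slab: str
    density_pct: dict[str, float]
    missing_zones: tuple[str, ...] = field(default_factory=tuple)
    method: str = "otsu"
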
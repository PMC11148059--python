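"""File I/O: images as 16-bit TIFF / 8-bit PNG, tables as CSV, metadata as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from ._containers import ChoroidBScanStack, EnFaceImage, SectorGrid

__all__ = [
    "save_enface", "load_enface",
    "save_label_map", "save_grid",
    "save_bscan_stack", "load_bscan_stack",
]


def save_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write an en face image; .tif/.tiff → 16-bit grayscale, .png → 8-bit."""
    path = Path(path)
    data = np.clip(image.data, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (data * 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        Image.fromarray((data * 255).round().astype(np.uint8)).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    meta = {"scale_um_per_px": image.scale_um_per_px, "modality": image.modality,
            "center_px": list(image.center_px)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_enface(path: str | Path, scale_um_per_px: float | None = None,
                modality: str | None = None) -> EnFaceImage:
    """Read an en face image, normalising intensities to [0, 1].

    A sidecar ``<name>.json`` written by :func:`save_enface` supplies the
    scale and modality when not given explicitly.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path).astype(float)
        data = raw / 65535.0 if raw.max() > 1 else raw
    else:
        raw = np.asarray(Image.open(path).convert("L"), dtype=float)
        data = raw / 255.0
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    scale = scale_um_per_px or meta.get("scale_um_per_px")
    if scale is None:
        raise ValueError("scale_um_per_px not given and no sidecar metadata found")
    return EnFaceImage(data, scale, modality=modality or meta.get("modality", "unknown"),
                       center_px=tuple(meta["center_px"]) if "center_px" in meta else None)


def save_label_map(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.int32))


def save_grid(grid: SectorGrid, stem: str | Path) -> None:
    """Write ``<stem>.tif`` (label map) and ``<stem>.json`` (zone legend)."""
    stem = Path(stem)
    save_label_map(grid.labels, stem.with_suffix(".tif"))
    legend = {
        "zones": {str(i + 1): name for i, name in enumerate(grid.zone_names)},
        "kind": grid.kind, "laterality": grid.laterality,
        "scale_um_per_px": grid.scale_um_per_px, "center_px": list(grid.center_px),
    }
    stem.with_suffix(".json").write_text(json.dumps(legend, indent=2))


def save_bscan_stack(stack: ChoroidBScanStack, stem: str | Path) -> None:
    """Write ``<stem>.tif`` (multipage B-scans), ``<stem>_traces.csv`` and a
    JSON sidecar with the scales."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tif"),
                     (np.clip(stack.bscans, 0, 1) * 65535).round().astype(np.uint16),
                     photometric="minisblack")
    rows = []
    for b in range(stack.n_bscans):
        for a in range(stack.n_ascans):
            rows.append((b, a, int(stack.bruch_trace[b, a]), int(stack.csi_trace[b, a])))
    pd.DataFrame(rows, columns=["bscan_idx", "ascan_idx", "bruch_row", "csi_row"]) \
        .to_csv(stem.parent / (stem.name + "_traces.csv"), index=False)
    meta = {"axial_um_per_px": stack.axial_um_per_px,
            "lateral_um_per_px": stack.lateral_um_per_px,
            "bscan_spacing_um": stack.bscan_spacing_um}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_bscan_stack(stem: str | Path) -> ChoroidBScanStack:
    stem = Path(stem)
    bscans = tifffile.imread(stem.with_suffix(".tif")).astype(float) / 65535.0
    traces = pd.read_csv(stem.parent / (stem.name + "_traces.csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    n_b, _, n_a = bscans.shape
    bruch = np.zeros((n_b, n_a), dtype=int)
    csi = np.zeros((n_b, n_a), dtype=int)
    bruch[traces.bscan_idx, traces.ascan_idx] = traces.bruch_row
    csi[traces.bscan_idx, traces.ascan_idx] = traces.csi_row
    return ChoroidBScanStack(bscans=bscans, bruch_trace=bruch, csi_trace=csi, **meta)
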
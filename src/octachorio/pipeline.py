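"""End-to-end study runner: simulate → quantify → compare → correlate → adjust.

`run_study` produces, inside an output directory:

* ``cohort.csv`` — the per-subject table (simulated or loaded);
* ``image_metrics.csv`` — flow-deficit metrics measured by the image
  pipeline on per-group synthetic CC/retina image pairs (image path);
* ``group_comparisons.csv``, ``correlations.csv``, ``regressions.csv`` —
  the three statistical tables;
* ``run_log.txt`` — every parameter value (defaults included) and seed.

The same configuration and seed reproduce every output byte (timestamps go
only to the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ccfd, stats
from ._containers import EnFaceImage
from .synthetic import (CCImageSpec, CohortConfig, default_cohort_config,
                        generate_cc_enface, generate_cohort, generate_retina_enface)

__all__ = ["RunConfig", "run_study", "EXIT_OK", "EXIT_CONFIG_ERROR", "EXIT_DATA_ERROR"]

logger = logging.getLogger("octachorio")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


@dataclass
class RunConfig:
    """Study-run configuration (YAML-serialisable)."""

    seed: int = 0
    n_per_group: int = 25
    cohort_csv: str | None = None  # use an existing table instead of simulating
    image_subjects_per_group: int = 2  # image-path demonstrations per group
    image_size_px: int = 256
    fd_density_pct: dict[str, float] = field(
        default_factory=lambda: {"pop1": 6.03, "pop2": 8.05})
    vessel_threshold: float = ccfd.DEFAULT_VESSEL_THRESHOLD
    min_equiv_diameter_um: float = ccfd.DEFAULT_MIN_EQUIV_DIAMETER_UM
    fcm_clusters: int = 2
    fcm_fuzziness: float = 2.0
    equal_var: bool = True
    bonferroni: bool = False
    out_dir: str = "octachorio_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _quantify_subject_image(group: str, idx: int, config: RunConfig) -> dict:
    spec = CCImageSpec(
        image_size_px=(config.image_size_px, config.image_size_px),
        target_fd_density_pct=config.fd_density_pct[group],
        seed=(config.seed * 1009 + sum(map(ord, group)) * 101 + idx) % (2**31),
    )
    cc, _ = generate_cc_enface(spec)
    retina, _ = generate_retina_enface(spec)
    metrics, fds, _ = ccfd.quantify_ccfd(
        cc, retina, vessel_threshold=config.vessel_threshold,
        min_equiv_diameter_um=config.min_equiv_diameter_um,
        clusters=config.fcm_clusters, fuzziness_m=config.fcm_fuzziness)
    return {"group": group, "image_idx": idx,
            "measured_fd_size_um2": metrics.mean_fd_size_um2,
            "measured_fd_density_pct": metrics.fd_density_pct,
            "measured_fd_count": metrics.fd_count,
            "planted_density_pct": spec.target_fd_density_pct}


def run_study(config: RunConfig, cohort_config: CohortConfig | None = None) -> Path:
    """Run the full study; returns the output directory path.

    ``cohort_config`` defaults to the packaged two-population parameters at
    ``config.n_per_group`` subjects per group.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run configuration (defaults included): %s",
                    json.dumps(asdict(config), sort_keys=True))
        if config.cohort_csv:
            table = pd.read_csv(config.cohort_csv)
            logger.info("loaded cohort from %s (%d subjects)",
                        config.cohort_csv, len(table))
        else:
            cc = cohort_config or default_cohort_config(
                seed=config.seed, n_per_group=config.n_per_group)
            table = generate_cohort(cc)
            logger.info("simulated cohort: %d per group, seed %d",
                        cc.n_per_group, cc.seed)
        table.to_csv(out / "cohort.csv", index=False)

        image_rows = []
        for group in sorted(table["group"].unique()):
            for idx in range(config.image_subjects_per_group):
                image_rows.append(_quantify_subject_image(group, idx, config))
                logger.info("image path: quantified %s image %d", group, idx)
        pd.DataFrame(image_rows).to_csv(out / "image_metrics.csv", index=False)

        metric_cols = [c for c in table.columns
                       if c not in ("subject_id", "group", "sex")]
        comparisons = stats.comparison_table(table, metric_cols,
                                             bonferroni=config.bonferroni)
        sex_res = stats.compare_sex(table)
        comparisons = pd.concat([comparisons, pd.DataFrame([{
            "variable": "sex", "test": sex_res.test,
            "statistic": sex_res.statistic, "p": sex_res.p_value,
            "significant": sex_res.significant}])], ignore_index=True)
        comparisons.to_csv(out / "group_comparisons.csv", index=False)

        corr_cols = [c for c in metric_cols
                     if c.startswith(("ccfd_", "ct_", "cvi_"))]
        stats.correlation_table(table, corr_cols, bonferroni=config.bonferroni) \
            .to_csv(out / "correlations.csv", index=False)
        stats.regression_table(table, corr_cols) \
            .to_csv(out / "regressions.csv", index=False)
        logger.info("wrote 4 output tables to %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def quantify_image_pair(cc: EnFaceImage, retina: EnFaceImage | None,
                        **kwargs) -> dict:
    """Thin functional wrapper used by the CLI's single-image subcommand."""
    metrics, fds, mask = ccfd.quantify_ccfd(cc, retina, **kwargs)
    return {"mean_fd_size_um2": metrics.mean_fd_size_um2,
            "fd_density_pct": metrics.fd_density_pct,
            "fd_count": metrics.fd_count,
            "analyzed_area_um2": metrics.analyzed_area_um2,
            "vessel_threshold": mask.threshold if mask else None}
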
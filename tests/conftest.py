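import warnings

import numpy as np
import pytest

from octachorio.grids import build_macular_grid
from octachorio.synthetic import (CCImageSpec, VariableSpec, CohortConfig,
                                  generate_cc_enface)

# Shapiro-Wilk p-values beyond n=5000 are approximate; harmless for gating.
warnings.filterwarnings("ignore",
                        message=r"scipy\.stats\.shapiro: For N > 5000.*")

SCALE = 6000.0 / 512.0  # µm per pixel of the default 6 × 6 mm field


@pytest.fixture(scope="session")
def macular_grid():
    """512-px macular grid over the full 6 × 6 mm field, right eye."""
    c = (512 - 1) / 2.0
    return build_macular_grid((c, c), (512, 512), SCALE, "OD")


@pytest.fixture(scope="session")
def clean_cc():
    """Noise-free CC image with planted deficits all ≥ 30 µm, plus truth."""
    spec = CCImageSpec(image_size_px=(256, 256), noise_sd=0.0,
                       fd_diameter_min_um=30.0, seed=11)
    return generate_cc_enface(spec)


def two_group_frame(a, b, extra=None):
    """Minimal cohort-style table from two value arrays."""
    import pandas as pd

    frame = pd.DataFrame({
        "group": ["pop1"] * len(a) + ["pop2"] * len(b),
        "value": np.concatenate([a, b]),
    })
    if extra:
        for k, v in extra.items():
            frame[k] = v
    return frame


def simple_config(r=None, mean1=(10.0, 2.0), mean2=(10.0, 2.0),
                  anchor_mean=(0.0, 1.0), n=100, seed=0, bounds=(None, None)):
    """Two-variable cohort config (anchor + one metric) for focused tests."""
    return CohortConfig(
        n_per_group=n,
        variables={
            "amt6s_pg_ml": VariableSpec(
                mean={"pop1": anchor_mean[0], "pop2": anchor_mean[0]},
                sd={"pop1": anchor_mean[1], "pop2": anchor_mean[1]}),
            "metric": VariableSpec(
                mean={"pop1": mean1[0], "pop2": mean2[0]},
                sd={"pop1": mean1[1], "pop2": mean2[1]}, bounds=bounds),
        },
        correlations_amt6s={} if r is None else {"metric": r},
        seed=seed,
    )
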
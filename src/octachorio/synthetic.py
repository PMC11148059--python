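"""Synthetic OCTA data with known ground truth.

Three generators emulate the inputs of the quantification pipeline so every
downstream stage can be tested without clinical data:

* granular choriocapillaris en face images with planted dark flow-deficit
  discs of controlled size distribution and total density, plus bright
  branching retinal vessel trees casting the large-vessel projection;
* choroid B-scan stacks with prescribed thickness profiles and luminal
  fraction;
* a two-population cohort table whose per-group means/SDs and pooled
  aMT6s–metric Pearson correlations are prescribed, induced through a
  one-factor Gaussian copula.

The copula takes the *pooled* correlation as its target: because the two
populations differ in their means, the within-group latent correlation that
reproduces a given pooled Pearson r is solved for analytically under the
two-group normal-mixture model (see docs/methods.md) and clamped to
[-1, 1] when the target is unattainable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from skimage import draw

from ._containers import ChoroidBScanStack, EnFaceImage

__all__ = [
    "CCImageSpec",
    "CCGroundTruth",
    "RetinaGroundTruth",
    "BScanGroundTruth",
    "InfeasibleDensityError",
    "generate_cc_enface",
    "generate_retina_enface",
    "generate_bscan_stack",
    "VariableSpec",
    "CohortConfig",
    "default_cohort_config",
    "generate_cohort",
    "load_study_parameters",
    "DEFAULT_SCALE_UM_PER_PX",
]

#: 512 px across a 6 × 6 mm field — typical swept-source sampling
DEFAULT_SCALE_UM_PER_PX = 6000.0 / 512.0

GROUPS = ("pop1", "pop2")


class InfeasibleDensityError(ValueError):
    """The requested flow-deficit density cannot be realised."""


# --------------------------------------------------------------------------
# en face image generators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CCImageSpec:
    """Parameters of a synthetic en face image.

    Flow deficits are non-overlapping discs with log-normally distributed
    diameters (given mean/SD in µm) planted until the requested density is
    reached.  ``fd_diameter_min_um`` optionally floors the distribution
    (rejection sampling), guaranteeing every planted deficit survives a
    diameter filter at that size.
    """

    image_size_px: tuple[int, int] = (512, 512)
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    fd_diameter_mean_um: float = 40.0
    fd_diameter_sd_um: float = 10.0
    fd_diameter_min_um: float | None = None
    target_fd_density_pct: float = 8.05
    background_intensity: float = 0.7
    fd_intensity: float = 0.2
    noise_sd: float = 0.02
    vessel_tree: bool = True
    n_branches: int = 4
    vessel_intensity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_fd_density_pct <= 100:
            raise ValueError("target_fd_density_pct must lie in [0, 100]")
        if self.fd_intensity >= self.background_intensity:
            raise ValueError("flow deficits must be darker than the background")
        if self.fd_diameter_mean_um <= 0 or self.fd_diameter_sd_um <= 0:
            raise ValueError("diameter mean and sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")


@dataclass
class CCGroundTruth:
    """Planted truth of a synthetic CC image."""

    fd_label_map: np.ndarray
    fd_table: pd.DataFrame  # label, center_row, center_col, nominal/measured size
    planted_density_pct: float


@dataclass
class RetinaGroundTruth:
    vessel_mask: np.ndarray


@dataclass
class BScanGroundTruth:
    thickness_map_um: np.ndarray
    luminal_mask: np.ndarray
    luminal_fraction: float


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_cc_enface(spec: CCImageSpec) -> tuple[EnFaceImage, CCGroundTruth]:
    """Granular CC en face image with planted dark flow-deficit discs.

    Discs are rejection-placed without overlap (with a 2-px separation so
    8-connected labelling keeps them distinct); planting stops once the
    pixel-measured density is within ±0.5 percentage points of the target
    (the final disc is shrunk to land inside the band).  Raises
    :class:`InfeasibleDensityError` when placement cannot reach the target.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    n_px = h * w
    target_px = spec.target_fd_density_pct / 100.0 * n_px
    band_px = 0.5 / 100.0 * n_px  # the ±0.5-point tolerance, in pixels

    mu, sigma = _lognormal_params(spec.fd_diameter_mean_um, spec.fd_diameter_sd_um)
    min_d = spec.fd_diameter_min_um or 2.0 * spec.scale_um_per_px

    def sample_diameter() -> float:
        for _ in range(10_000):
            d = float(rng.lognormal(mu, sigma))
            if d >= min_d:
                return d
        raise InfeasibleDensityError(
            "diameter floor rejects essentially the whole diameter distribution"
        )

    label_map = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    records: list[dict] = []
    planted_px = 0
    label = 0
    # 1.5-px edge separation: the closest allowed pixel pair is Chebyshev-2,
    # so 8-connected labelling keeps planted discs distinct
    gap_px = 1.5

    while target_px - planted_px > 0.5:
        d_um = sample_diameter()
        r_px = d_um / (2.0 * spec.scale_um_per_px)
        # shrink the closing disc so the final density stays inside the band
        if math.pi * r_px**2 > (target_px - planted_px) + 0.9 * band_px:
            needed = target_px - planted_px
            if needed <= 0.9 * band_px:
                break
            r_fill = math.sqrt(needed / math.pi)
            r_min = min_d / (2.0 * spec.scale_um_per_px)
            if r_fill < r_min:
                if math.pi * r_min**2 - needed <= 0.9 * band_px:
                    r_px = r_min
                else:
                    raise InfeasibleDensityError(
                        "minimum deficit size overshoots the density tolerance"
                    )
            else:
                r_px = r_fill
            d_um = 2.0 * r_px * spec.scale_um_per_px
        placed = False
        for _ in range(500):
            margin = r_px + gap_px
            if 2 * margin >= min(h, w):
                break
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            rr_d, cc_d = draw.disk((cy, cx), r_px, shape=(h, w))
            if occupied[rr_d, cc_d].any():
                continue
            if rr_d.size == 0:
                rr_d = np.array([int(round(cy))])
                cc_d = np.array([int(round(cx))])
                if occupied[rr_d, cc_d].any():
                    continue
            label += 1
            label_map[rr_d, cc_d] = label
            rr_o, cc_o = draw.disk((cy, cx), r_px + gap_px, shape=(h, w))
            occupied[rr_o, cc_o] = True
            planted_px += rr_d.size
            records.append({
                "label": label, "center_row": cy, "center_col": cx,
                "nominal_diameter_um": d_um,
                "area_um2": rr_d.size * spec.scale_um_per_px**2,
                "equiv_diameter_um": 2.0 * math.sqrt(
                    rr_d.size * spec.scale_um_per_px**2 / math.pi),
            })
            placed = True
            break
        if not placed:
            raise InfeasibleDensityError(
                f"could not place a {d_um:.1f}-µm deficit at density "
                f"{100 * planted_px / n_px:.2f}% (target {spec.target_fd_density_pct}%)"
            )

    image = np.full((h, w), spec.background_intensity, dtype=float)
    image[label_map > 0] = spec.fd_intensity
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    columns = ["label", "center_row", "center_col", "nominal_diameter_um",
               "area_um2", "equiv_diameter_um"]
    truth = CCGroundTruth(
        fd_label_map=label_map,
        fd_table=pd.DataFrame(records, columns=columns),
        planted_density_pct=100.0 * planted_px / n_px,
    )
    enface = EnFaceImage(image, spec.scale_um_per_px, modality="CC")
    return enface, truth


def _draw_branch(mask: np.ndarray, rng: np.random.Generator, start: np.ndarray,
                 angle: float, length: float, width: float, depth: int) -> None:
    """Stamp a randomly wandering vessel segment and recurse into children."""
    h, w = mask.shape
    pos = start.astype(float)
    step = 3.0
    n_steps = max(1, int(length / step))
    for _ in range(n_steps):
        angle += rng.normal(0.0, 0.12)
        pos = pos + step * np.array([math.sin(angle), math.cos(angle)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            return
        rr, cc = draw.disk(tuple(pos), max(width, 1.0), shape=(h, w))
        mask[rr, cc] = True
    if depth > 0 and width > 1.2:
        spread = rng.uniform(0.3, 0.7)
        for sign in (-1.0, 1.0):
            _draw_branch(mask, rng, pos, angle + sign * spread,
                         length * 0.7, width * 0.7, depth - 1)


def generate_retina_enface(spec: CCImageSpec) -> tuple[EnFaceImage, RetinaGroundTruth]:
    """Retinal composite slab: bright branching vessel tree on dark background.

    Vessel pixels take ``spec.vessel_intensity`` (above the default 0.6
    fixed binarisation threshold) with hard edges, so a noise-free image
    binarises exactly back to the ground-truth mask.
    """
    if not spec.vessel_tree and spec.n_branches > 0:
        raise ValueError("vessel_tree is disabled for this spec")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_branches):
        edge = rng.integers(4)
        if edge == 0:  # top edge, heading down (+row)
            start = np.array([0.0, rng.uniform(0, w - 1)])
            angle = math.pi / 2 + rng.uniform(-0.5, 0.5)
        elif edge == 1:  # bottom edge, heading up
            start = np.array([float(h - 1), rng.uniform(0, w - 1)])
            angle = -math.pi / 2 + rng.uniform(-0.5, 0.5)
        elif edge == 2:  # left edge, heading right (+col)
            start = np.array([rng.uniform(0, h - 1), 0.0])
            angle = rng.uniform(-0.5, 0.5)
        else:  # right edge, heading left
            start = np.array([rng.uniform(0, h - 1), float(w - 1)])
            angle = math.pi + rng.uniform(-0.5, 0.5)
        _draw_branch(mask, rng, start, angle, length=0.8 * max(h, w),
                     width=4.0, depth=4)
    image = np.full((h, w), 0.3, dtype=float)
    image[mask] = spec.vessel_intensity
    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, size=image.shape),
                        0.0, 1.0)
    enface = EnFaceImage(image, spec.scale_um_per_px, modality="retina")
    return enface, RetinaGroundTruth(vessel_mask=mask)


def generate_bscan_stack(thickness_profile_um: np.ndarray, luminal_fraction: float,
                         *, axial_um_per_px: float = 3.0,
                         lateral_um_per_px: float = DEFAULT_SCALE_UM_PER_PX,
                         bscan_spacing_um: float = DEFAULT_SCALE_UM_PER_PX,
                         n_bscans: int | None = None, noise_sd: float = 0.0,
                         stroma_intensity: float = 0.8,
                         lumen_intensity: float = 0.2,
                         seed: int = 0) -> tuple[ChoroidBScanStack, BScanGroundTruth]:
    """Choroid B-scan stack with known thickness profile and luminal fraction.

    ``thickness_profile_um`` is either per-A-scan (1-D, broadcast over
    ``n_bscans`` B-scans) or a full ``(n_bscans, n_ascans)`` map.  Luminal
    vessels are small dark discs (radius 2–6 px) scattered inside the
    choroid band until the requested area fraction is reached; the rest of
    the B-scan is stroma-bright, which keeps every Niblack window bimodal.
    """
    if not 0.0 <= luminal_fraction <= 1.0:
        raise ValueError("luminal_fraction must lie in [0, 1]")
    profile = np.asarray(thickness_profile_um, dtype=float)
    if profile.ndim == 1:
        profile = np.tile(profile, ((n_bscans or 32), 1))
    elif n_bscans is not None and profile.shape[0] != n_bscans:
        raise ValueError("n_bscans conflicts with 2-D thickness profile")
    if (profile <= 0).any():
        raise ValueError("thickness profile must be positive everywhere")
    n_b, n_a = profile.shape

    rng = np.random.default_rng(seed)
    bruch_row = 10
    band_height = np.rint(profile / axial_um_per_px).astype(int)
    band_height = np.maximum(band_height, 1)
    n_rows = bruch_row + int(band_height.max()) + 10
    bruch = np.full((n_b, n_a), bruch_row, dtype=int)
    csi = bruch + band_height

    bscans = np.full((n_b, n_rows, n_a), stroma_intensity, dtype=float)
    stack = ChoroidBScanStack(bscans=bscans, bruch_trace=bruch, csi_trace=csi,
                              axial_um_per_px=axial_um_per_px,
                              lateral_um_per_px=lateral_um_per_px,
                              bscan_spacing_um=bscan_spacing_um)
    band = stack.band_mask()
    band_total = int(band.sum())
    lumen = np.zeros_like(band)
    if luminal_fraction >= 1.0:
        lumen = band.copy()
    elif luminal_fraction > 0.0:
        # Fixed-radius luminal discs on a jittered square lattice whose cell
        # pitch is sized so per-cell disc coverage equals the requested
        # fraction: coverage is then spatially uniform, not just on average.
        r = 3.0
        # translation-averaged pixel count of a rasterised disc is exactly πr²
        disc_px = math.pi * r**2
        n_lumen = 0
        target = luminal_fraction * band_total
        if luminal_fraction <= disc_px / (2.0 * r) ** 2:  # pitch >= 2r
            pitch = math.sqrt(disc_px / luminal_fraction)
            jitter = (pitch - 2.0 * r) / 2.0
            for b in range(n_b):
                n_rows_band = int(band_height[b].max())
                for gy in np.arange(bruch_row + pitch / 2.0,
                                    bruch_row + n_rows_band, pitch):
                    for gx in np.arange(pitch / 2.0, n_a, pitch):
                        cy = gy + rng.uniform(-jitter, jitter)
                        cx = gx + rng.uniform(-jitter, jitter)
                        rr, cc = draw.disk((cy, cx), r, shape=(n_rows, n_a))
                        sel = band[b, rr, cc]
                        lumen[b, rr[sel], cc[sel]] = True
                        n_lumen += int(sel.sum())
        else:
            # discs on a square lattice cannot exceed ~π/4 coverage
            lumen[band] = rng.random(band_total) < luminal_fraction
            n_lumen = int(lumen.sum())
        # top up the edge-clipping deficit with small scattered discs
        guard = 0
        while n_lumen < target:
            b = int(rng.integers(n_b))
            row = float(rng.uniform(bruch_row, bruch_row + band_height[b].max()))
            col = float(rng.uniform(-2.0, n_a + 1.0))
            rr, cc = draw.disk((row, col), 1.5, shape=(n_rows, n_a))
            sel = band[b, rr, cc] & ~lumen[b, rr, cc]
            n_lumen += int(sel.sum())
            lumen[b, rr[sel], cc[sel]] = True
            guard += 1
            if guard > 2_000_000:  # pragma: no cover
                raise RuntimeError("luminal placement failed to converge")
    stack.bscans[lumen] = lumen_intensity
    if noise_sd > 0:
        stack.bscans = np.clip(
            stack.bscans + rng.normal(0.0, noise_sd, size=stack.bscans.shape), 0, 1)
    stack.luminal_mask = lumen
    truth = BScanGroundTruth(thickness_map_um=band_height * axial_um_per_px,
                             luminal_mask=lumen,
                             luminal_fraction=float(lumen.sum()) / band_total)
    return stack, truth


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Per-group normal marginal with physical bounds for one variable."""

    mean: dict[str, float]
    sd: dict[str, float]
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd.values()):
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic two-population cohort.

    ``correlations_amt6s`` maps metric column names to the pooled Pearson
    correlation with the anchor variable (aMT6s).  ``nearest_psd_repair``
    enables eigenvalue clipping of a non-positive-semi-definite latent
    correlation matrix instead of raising.
    """

    n_per_group: int = 25
    variables: dict[str, VariableSpec] = field(default_factory=dict)
    correlations_amt6s: dict[str, float] = field(default_factory=dict)
    male_fraction: dict[str, float] = field(default_factory=lambda: {g: 0.5 for g in GROUPS})
    anchor: str = "amt6s_pg_ml"
    seed: int = 0
    nearest_psd_repair: bool = False

    def with_(self, **changes) -> "CohortConfig":
        return replace(self, **changes)


def load_study_parameters() -> dict:
    """Raw packaged default-parameter table (one entry per study table cell)."""
    text = resources.files("octachorio").joinpath("data/study_parameters.yaml").read_text()
    return yaml.safe_load(text)


def default_cohort_config(seed: int = 0, n_per_group: int | None = None) -> CohortConfig:
    """Default cohort: two populations of 25, marginals and correlations from
    the packaged parameter table."""
    params = load_study_parameters()
    variables: dict[str, VariableSpec] = {}

    def add(name: str, entry: dict) -> None:
        bounds = entry.get("bounds", [None, None])
        variables[name] = VariableSpec(
            mean={g: float(entry[g][0]) for g in GROUPS},
            sd={g: float(entry[g][1]) for g in GROUPS},
            bounds=(bounds[0], bounds[1]),
        )

    demo = params["demographics"]
    add("age", demo["age_years"])
    add("iop_mmHg", demo["iop_mmHg"])
    add("ser_D", demo["ser_D"])
    add("al_mm", demo["al_mm"])
    for name, entry in params["variables"].items():
        add(name, entry)
    return CohortConfig(
        n_per_group=n_per_group or int(params["n_per_group"]),
        variables=variables,
        correlations_amt6s={k: float(v) for k, v in params["correlations_amt6s"].items()},
        male_fraction={g: float(demo["male_fraction"][g]) for g in GROUPS},
        seed=seed,
    )


def _clipped_normal_mean(mu: float, sigma: float, lo: float | None,
                         hi: float | None) -> float:
    """Mean of clip(N(mu, sigma²), lo, hi) in closed form."""
    from scipy.stats import norm

    a = -np.inf if lo is None else (lo - mu) / sigma
    b = np.inf if hi is None else (hi - mu) / sigma
    val = mu * (norm.cdf(b) - norm.cdf(a)) + sigma * (norm.pdf(a) - norm.pdf(b))
    if lo is not None:
        val += lo * norm.cdf(a)
    if hi is not None:
        val += hi * (1.0 - norm.cdf(b))
    return float(val)


def _latent_location(target_mean: float, sigma: float, lo: float | None,
                     hi: float | None) -> float:
    """Location of the latent normal whose *clipped* mean equals the target.

    Clipping at a physical bound shifts the observed mean away from the
    latent location; the shift is inverted here so configured means are the
    means of what the generator actually emits.  No-op when the bounds sit
    far (> 6 SD) from the target or the SD is zero.
    """
    if sigma == 0:
        return target_mean
    far_lo = lo is None or target_mean - lo > 6 * sigma
    far_hi = hi is None or hi - target_mean > 6 * sigma
    if far_lo and far_hi:
        return target_mean
    from scipy.optimize import brentq

    return float(brentq(
        lambda mu: _clipped_normal_mean(mu, sigma, lo, hi) - target_mean,
        target_mean - 10 * sigma, target_mean + 10 * sigma, xtol=1e-10))


def _calibrate_latent_rho(config: CohortConfig, name: str, r_target: float) -> float:
    """Within-group latent correlation reproducing a pooled Pearson target.

    Under the equal-size two-group normal mixture,
    ``Var(x) = mean(sd_g²) + (Δm/2)²`` and
    ``Cov(x, y) = ρ_w · mean(sd_x,g sd_y,g) + Δm_x Δm_y / 4``;
    solving for ``ρ_w`` and clamping to [-1, 1].
    """
    x = config.variables[config.anchor]
    y = config.variables[name]
    dx = x.mean["pop1"] - x.mean["pop2"]
    dy = y.mean["pop1"] - y.mean["pop2"]
    var_x = (x.sd["pop1"] ** 2 + x.sd["pop2"] ** 2) / 2.0 + dx**2 / 4.0
    var_y = (y.sd["pop1"] ** 2 + y.sd["pop2"] ** 2) / 2.0 + dy**2 / 4.0
    within = (x.sd["pop1"] * y.sd["pop1"] + x.sd["pop2"] * y.sd["pop2"]) / 2.0
    if within == 0:
        return 0.0
    rho = (r_target * math.sqrt(var_x * var_y) - dx * dy / 4.0) / within
    return float(np.clip(rho, -1.0, 1.0))


def _latent_factor(config: CohortConfig, names: list[str]) -> np.ndarray:
    """Factor L with L·Lᵀ = latent correlation matrix (eigendecomposition,
    tolerant of the singular ρ = ±1 case)."""
    rhos = {}
    for name, r in config.correlations_amt6s.items():
        if name not in config.variables:
            raise KeyError(f"correlation refers to unknown variable {name!r}")
        if abs(r) > 1:
            raise ValueError("invalid correlation matrix: |r| > 1")
        rhos[name] = _calibrate_latent_rho(config, name, r)
    d = len(names)
    corr = np.eye(d)
    ai = names.index(config.anchor)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if i == j:
                continue
            if i == ai:
                corr[i, j] = rhos.get(nj, 0.0)
            elif j == ai:
                corr[i, j] = rhos.get(ni, 0.0)
            else:
                corr[i, j] = rhos.get(ni, 0.0) * rhos.get(nj, 0.0)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        if not config.nearest_psd_repair:
            raise ValueError("invalid correlation matrix: not positive semi-definite")
        eigval = np.clip(eigval, 0.0, None)
    return eigvec * np.sqrt(np.clip(eigval, 0.0, None))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample the synthetic cohort table.

    Returns one row per subject with columns ``subject_id, group, age, sex,
    iop_mmHg, ser_D, al_mm, amt6s_pg_ml`` followed by the metric columns, in
    the configuration's variable order.  Identical config (including seed)
    gives a bitwise-identical table.
    """
    if config.n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    if config.anchor not in config.variables:
        raise KeyError(f"anchor variable {config.anchor!r} missing from variables")
    names = list(config.variables)
    factor = _latent_factor(config, names)
    rng = np.random.default_rng(config.seed)

    frames = []
    for g_idx, group in enumerate(GROUPS):
        n = config.n_per_group
        z = rng.standard_normal((n, len(names))) @ factor.T
        data: dict[str, np.ndarray] = {}
        for j, name in enumerate(names):
            spec = config.variables[name]
            lo, hi = spec.bounds
            loc = _latent_location(spec.mean[group], spec.sd[group], lo, hi)
            x = loc + spec.sd[group] * z[:, j]
            x = np.clip(x, -np.inf if lo is None else lo, np.inf if hi is None else hi)
            data[name] = x
        n_male = int(round(config.male_fraction[group] * n))
        sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sex)
        frame = pd.DataFrame(data)
        frame.insert(0, "sex", sex)
        frame.insert(0, "group", group)
        frame.insert(0, "subject_id", [f"{group}-{i + 1:05d}" for i in range(n)])
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    lead = ["subject_id", "group", "age", "sex", "iop_mmHg", "ser_D", "al_mm",
            config.anchor]
    lead = [c for c in lead if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    return table[lead + rest]
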
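# octachorio

Quantification of the choriocapillaris and choroid from en face OCT
angiography (OCTA), built for studies that compare ocular microvascular
parameters between two groups of subjects and relate them to a biochemical
covariate (urinary 6-sulfatoxymelatonin, aMT6s, a proxy for circulating
melatonin).

The package implements, as reusable and tested components:

* **Choriocapillaris flow deficits (CC FD).** A large-vessel projection
  mask is taken from the retinal composite slab by fixed-threshold
  binarisation and excluded from analysis; fuzzy C-means (FCM) clustering
  of the remaining CC intensities labels the darkest cluster as flow
  deficit; 8-connected components with equivalent diameter
  d = 2·√(A/π) < 24 µm (the nominal intercapillary distance) are discarded.
  Reported indices: **mean FD size** (µm²) and **FD density**
  (% of the analysed area).
* **Sector grids.** The nine-zone macular grid (1 / 3 / 6 mm circles;
  fovea + parafoveal and perifoveal S/I/N/T quadrants split along the 45°
  diagonals) and the nine-zone peripapillary grid (optic disc + a 2-mm-wide
  ring in eight 45° sectors), laterality-aware, as labelled pixel masks.
* **Choroidal thickness (CT) and choroidal vascularity index (CVI)** from
  boundary-annotated B-scan stacks: CT is the Bruch's-membrane to
  choroid–sclera distance; CVI is the luminal fraction of the choroid band
  after Niblack binarisation, pooled per macular zone.
* **Vessel density** (% vessel pixels) per zone for any en face slab
  (SCP / DCP / RPC / CC), Otsu-binarised by default.
* **Cohort statistics.** Shapiro–Wilk-gated two-group comparisons
  (t-test / Mann–Whitney U), gated correlations (Pearson / Spearman) of
  aMT6s with the choroidal metrics, and OLS multivariable models adjusting
  for age, axial length and spherical equivalent.
* **Synthetic data with ground truth.** Granular CC images with planted
  dark deficits of controlled size distribution and density, branching
  retinal vessel trees, choroid B-scan stacks with known thickness and
  luminal fraction, and a Gaussian-copula cohort simulator whose
  per-population means/SDs and pooled aMT6s correlations are configured
  from a packaged parameter table.

No clinical images or subject data ship with the package; every pipeline
stage is exercised against the synthetic generators.

## Worked example

```python
import numpy as np
from octachorio import (CCImageSpec, generate_cc_enface, generate_retina_enface,
                        quantify_ccfd, default_cohort_config, generate_cohort,
                        compare_groups, correlate, multivariable_fit)

# --- image path: plant deficits at 8.05 % density, then measure them back
spec = CCImageSpec(target_fd_density_pct=8.05, seed=7)
cc, truth = generate_cc_enface(spec)
retina, _ = generate_retina_enface(spec)
metrics, fds, mask = quantify_ccfd(cc, retina)
print(f"planted FD density : {truth.planted_density_pct:.2f} %")
print(f"measured FD density: {metrics.fd_density_pct:.2f} %")

# --- cohort path: two populations of 25, packaged study parameters
table = generate_cohort(default_cohort_config(seed=0))
res = compare_groups(table, "amt6s_pg_ml")
print(f"aMT6s: {res.group_means['pop1']:.1f} vs {res.group_means['pop2']:.1f} "
      f"pg/ml, {res.test}-test p = {res.p_value:.4g}")
corr = correlate(table, "cvi_3S")
print(f"aMT6s ~ CVI 3-S: {corr.method} r = {corr.r:.3f}, p = {corr.p_value:.4g}")
fit = multivariable_fit(table, "cvi_3S")
print(f"adjusted aMT6s coefficient: {fit.coefficients['amt6s_pg_ml']:.2e}, "
      f"p = {fit.p_values['amt6s_pg_ml']:.4g}")
```

prints

```
planted FD density : 8.05 %
measured FD density: 7.97 %
aMT6s: 136.7 vs 213.4 pg/ml, t-test p = 0.0001516
aMT6s ~ CVI 3-S: pearson r = 0.451, p = 0.001006
adjusted aMT6s coefficient: 2.40e-04, p = 0.002133
```

The measured density sits within a tenth of a point of the plant (the small
deficit comes from components hidden under the vessel projection and the
24-µm filter). In the simulated cohort the melatonin metabolite differs
strongly between populations, correlates positively with the perifoveal
superior CVI, and the association survives adjustment for age, axial length
and spherical equivalent — the qualitative pattern the default parameter
table encodes.

A CLI mirrors the library: `octachorio simulate {cc|retina|bscan|cohort}`,
`octachorio grid {macula|disc}`, `octachorio ccfd`, `octachorio density`,
and `octachorio run --config study.yaml` for a full simulate → quantify →
statistics run with a reproducible log.

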
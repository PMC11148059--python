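# Default parameters of the synthetic two-population cohort.
#
# Populations are labelled positionally (pop1 = first-listed, pop2 = second-listed)
# rather than semantically.  Each variable entry is  {pop1: [mean, sd], pop2: [mean, sd]}
# with physical bounds used to clip draws.  `correlations_amt6s` holds the pooled
# Pearson correlation of each metric with urinary 6-sulfatoxymelatonin (aMT6s).
n_per_group: 25
demographics:
  age_years:
    pop1: [30.88, 1.81]
    pop2: [29.68, 3.56]
    bounds: [18, null]
  iop_mmHg:
    pop1: [14.67, 1.62]
    pop2: [15.44, 1.70]
    bounds: [5, null]
  ser_D:
    pop1: [-0.46, 0.80]
    pop2: [-0.31, 0.53]
    bounds: [-3, 3]
  al_mm:
    pop1: [23.94, 0.73]
    pop2: [23.92, 0.72]
    bounds: [20, null]
  male_fraction:
    pop1: 0.40   # 10 / 25
    pop2: 0.48   # 12 / 25
variables:
  amt6s_pg_ml:
    pop1: [138.90, 74.80]
    pop2: [218.85, 78.10]
    bounds: [0, null]
  # The flow-deficit pair is assigned by the study's stated direction
  # (pop1, the low-aMT6s population, has the lower FD size/density), which is
  # also the only assignment consistent with the positive pooled aMT6s-FD
  # correlation below.
  ccfd_size_um2:
    pop1: [25.80, 2.01]
    pop2: [32.22, 4.60]
    bounds: [0, null]
  ccfd_density_pct:
    pop1: [6.03, 1.44]
    pop2: [8.05, 1.93]
    bounds: [0, 100]
  # Superficial capillary plexus vessel density (%)
  vd_scp_fovea: {pop1: [9.96, 4.22], pop2: [8.74, 5.14], bounds: [0, 100]}
  vd_scp_2I: {pop1: [50.58, 4.11], pop2: [48.97, 4.51], bounds: [0, 100]}
  vd_scp_2T: {pop1: [41.41, 5.07], pop2: [39.13, 5.05], bounds: [0, 100]}
  vd_scp_2S: {pop1: [51.41, 4.79], pop2: [48.62, 4.33], bounds: [0, 100]}
  vd_scp_2N: {pop1: [46.41, 3.63], pop2: [44.92, 3.24], bounds: [0, 100]}
  vd_scp_3I: {pop1: [45.04, 3.29], pop2: [43.86, 3.33], bounds: [0, 100]}
  vd_scp_3T: {pop1: [34.20, 5.16], pop2: [32.24, 2.77], bounds: [0, 100]}
  vd_scp_3S: {pop1: [39.72, 4.15], pop2: [38.37, 3.68], bounds: [0, 100]}
  vd_scp_3N: {pop1: [48.78, 4.49], pop2: [45.72, 3.37], bounds: [0, 100]}
  # Deep capillary plexus vessel density (%)
  vd_dcp_fovea: {pop1: [1.51, 1.06], pop2: [2.32, 2.02], bounds: [0, 100]}
  vd_dcp_2I: {pop1: [6.76, 3.47], pop2: [8.80, 4.88], bounds: [0, 100]}
  vd_dcp_2T: {pop1: [8.06, 4.75], pop2: [10.84, 4.47], bounds: [0, 100]}
  vd_dcp_2S: {pop1: [7.37, 3.86], pop2: [8.11, 4.19], bounds: [0, 100]}
  vd_dcp_2N: {pop1: [6.97, 2.80], pop2: [7.88, 4.96], bounds: [0, 100]}
  vd_dcp_3I: {pop1: [14.46, 5.10], pop2: [13.38, 5.08], bounds: [0, 100]}
  vd_dcp_3T: {pop1: [19.04, 7.19], pop2: [21.20, 7.29], bounds: [0, 100]}
  vd_dcp_3S: {pop1: [14.00, 5.45], pop2: [13.14, 6.50], bounds: [0, 100]}
  vd_dcp_3N: {pop1: [11.11, 5.97], pop2: [10.07, 6.04], bounds: [0, 100]}
  # Radial peripapillary capillary vessel density (%)
  vd_rpc_inside_disc: {pop1: [90.20, 2.45], pop2: [91.86, 2.80], bounds: [0, 100]}
  vd_rpc_NS: {pop1: [53.66, 11.76], pop2: [49.16, 8.38], bounds: [0, 100]}
  vd_rpc_NI: {pop1: [47.37, 11.01], pop2: [48.69, 14.43], bounds: [0, 100]}
  vd_rpc_IN: {pop1: [70.13, 7.93], pop2: [64.36, 9.51], bounds: [0, 100]}
  vd_rpc_IT: {pop1: [80.12, 5.05], pop2: [79.16, 7.42], bounds: [0, 100]}
  vd_rpc_TI: {pop1: [49.09, 12.49], pop2: [52.04, 15.80], bounds: [0, 100]}
  vd_rpc_TS: {pop1: [51.56, 12.10], pop2: [46.05, 16.23], bounds: [0, 100]}
  vd_rpc_ST: {pop1: [77.34, 5.69], pop2: [75.11, 8.99], bounds: [0, 100]}
  vd_rpc_SN: {pop1: [74.34, 6.10], pop2: [72.39, 6.89], bounds: [0, 100]}
  # Choriocapillaris vessel density (%)
  vd_cc_fovea: {pop1: [72.03, 4.70], pop2: [72.09, 6.75], bounds: [0, 100]}
  vd_cc_2I: {pop1: [69.77, 7.37], pop2: [72.12, 5.38], bounds: [0, 100]}
  vd_cc_2T: {pop1: [70.88, 5.42], pop2: [70.44, 7.23], bounds: [0, 100]}
  vd_cc_2S: {pop1: [72.77, 5.93], pop2: [72.70, 4.99], bounds: [0, 100]}
  vd_cc_2N: {pop1: [71.38, 5.17], pop2: [69.62, 7.29], bounds: [0, 100]}
  vd_cc_3I: {pop1: [75.01, 3.57], pop2: [73.93, 3.48], bounds: [0, 100]}
  vd_cc_3T: {pop1: [70.29, 8.42], pop2: [71.10, 9.20], bounds: [0, 100]}
  vd_cc_3S: {pop1: [72.05, 3.66], pop2: [72.51, 4.16], bounds: [0, 100]}
  vd_cc_3N: {pop1: [73.63, 5.15], pop2: [71.88, 5.12], bounds: [0, 100]}
  # Choroidal thickness (µm)
  ct_fovea: {pop1: [436.85, 57.67], pop2: [282.05, 56.97], bounds: [0, null]}
  ct_2I: {pop1: [457.68, 75.16], pop2: [290.44, 59.33], bounds: [0, null]}
  ct_2T: {pop1: [456.66, 59.05], pop2: [291.32, 53.13], bounds: [0, null]}
  ct_2S: {pop1: [465.06, 72.84], pop2: [281.60, 63.47], bounds: [0, null]}
  ct_2N: {pop1: [423.63, 80.90], pop2: [251.12, 60.23], bounds: [0, null]}
  ct_3I: {pop1: [466.44, 95.52], pop2: [302.33, 60.30], bounds: [0, null]}
  ct_3T: {pop1: [461.46, 91.19], pop2: [291.64, 44.76], bounds: [0, null]}
  ct_3S: {pop1: [468.77, 109.19], pop2: [285.70, 55.57], bounds: [0, null]}
  ct_3N: {pop1: [383.27, 121.51], pop2: [198.14, 56.01], bounds: [0, null]}
  # Choroidal vascularity index (unitless)
  cvi_fovea: {pop1: [0.34, 0.05], pop2: [0.42, 0.06], bounds: [0, 1]}
  cvi_2I: {pop1: [0.35, 0.04], pop2: [0.40, 0.06], bounds: [0, 1]}
  cvi_2T: {pop1: [0.34, 0.04], pop2: [0.41, 0.05], bounds: [0, 1]}
  cvi_2S: {pop1: [0.34, 0.04], pop2: [0.42, 0.05], bounds: [0, 1]}
  cvi_2N: {pop1: [0.37, 0.05], pop2: [0.43, 0.06], bounds: [0, 1]}
  cvi_3I: {pop1: [0.32, 0.02], pop2: [0.37, 0.05], bounds: [0, 1]}
  cvi_3T: {pop1: [0.31, 0.03], pop2: [0.37, 0.04], bounds: [0, 1]}
  cvi_3S: {pop1: [0.32, 0.04], pop2: [0.38, 0.04], bounds: [0, 1]}
  cvi_3N: {pop1: [0.35, 0.04], pop2: [0.41, 0.05], bounds: [0, 1]}
# Pooled Pearson correlation of each metric with aMT6s concentration.
correlations_amt6s:
  ccfd_size_um2: 0.318
  ccfd_density_pct: 0.147
  ct_fovea: -0.477
  ct_2I: -0.434
  ct_2T: -0.454
  ct_2S: -0.432
  ct_2N: -0.437
  ct_3I: -0.424
  ct_3T: -0.376
  ct_3S: -0.396
  ct_3N: -0.459
  cvi_fovea: 0.318
  cvi_2I: 0.209
  cvi_2T: 0.439
  cvi_2S: 0.464
  cvi_2N: 0.275
  cvi_3I: 0.312
  cvi_3T: 0.449
  cvi_3S: 0.482
  cvi_3N: 0.400
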
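# Fog-forest-like synthetic design: 5 trees x 3 zones x 4 patches (2 small,
# 2 large).  Zone means are the published large-patch zone means (averaged
# over the two large patches); CVs are the published per-zone large-patch
# CVs; trait correlations are the published per-zone 5x5 matrices over
# SD, TD, LMA, VD, VDi.  SM and water-potential CVs are not reported in
# the study tables; 0.25 is a realistic field-scale choice (documented in
# docs/methods.md).  Small patches reuse large-patch windward/core-like
# values with no zone correlation structure, mirroring the weaker zone
# differentiation observed in small patches.
#
# Units: SM %, psi_* MPa (positive magnitude of -psi), SD mm^-2, TD mm^-2,
# LMA g m^-2, VD mm^-2, VDi um, Ks kg m^-1 s^-1 MPa^-1.

seed: 20100101

defaults: &zone_defaults
  n_trees: 5
  within_tree_cv: 0.1
  n_replicates:
    LMA: 10
    SM: 5
    psi_PD: 5
    psi_MD: 5

correlations:
  windward: &corr_windward
    traits: [SD, TD, LMA, VD, VDi]
    upper_triangle: [0.55, -0.03, -0.56, 0.16, -0.22, -0.76, 0.11, 0.00, -0.27, -0.16]
  core: &corr_core
    traits: [SD, TD, LMA, VD, VDi]
    upper_triangle: [0.34, -0.87, 0.04, 0.01, -0.25, 0.04, 0.05, -0.18, 0.06, -0.90]
  leeward: &corr_leeward
    traits: [SD, TD, LMA, VD, VDi]
    upper_triangle: [0.74, -0.75, 0.32, -0.29, -0.76, 0.41, -0.46, -0.75, 0.63, -0.73]

zone_means:
  windward: &means_windward
    SM: 9.25
    psi_PD: 0.145
    psi_MD: 0.725
    SD: 108.0
    TD: 4.7
    LMA: 150.5
    VD: 285.0
    VDi: 17.95
    Ks: 0.41
  core: &means_core
    SM: 14.6
    psi_PD: 0.10
    psi_MD: 0.71
    SD: 123.0
    TD: 5.0
    LMA: 139.0
    VD: 302.0
    VDi: 16.7
    Ks: 0.365
  leeward: &means_leeward
    SM: 4.7
    psi_PD: 0.825
    psi_MD: 1.71
    SD: 170.5
    TD: 10.7
    LMA: 273.0
    VD: 309.5
    VDi: 16.9
    Ks: 0.10

zone_cvs:
  windward: &cvs_windward
    SD: 0.05
    TD: 0.20
    LMA: 0.30
    VD: 0.12
    VDi: 0.06
    Ks: 0.28
    SM: 0.25
    psi_PD: 0.25
    psi_MD: 0.25
  core: &cvs_core
    SD: 0.11
    TD: 0.16
    LMA: 0.34
    VD: 0.12
    VDi: 0.09
    Ks: 0.27
    SM: 0.25
    psi_PD: 0.25
    psi_MD: 0.25
  leeward: &cvs_leeward
    SD: 0.21
    TD: 0.29
    LMA: 0.27
    VD: 0.12
    VDi: 0.07
    Ks: 0.72
    SM: 0.25
    psi_PD: 0.25
    psi_MD: 0.25

patches:
  - patch_id: P1
    size_class: small
    zones:
      windward:
        <<: *zone_defaults
        trait_means: *means_windward
        trait_cvs: *cvs_windward
      core:
        <<: *zone_defaults
        trait_means: *means_core
        trait_cvs: *cvs_core
      leeward:
        <<: *zone_defaults
        trait_means: *means_core
        trait_cvs: *cvs_core
  - patch_id: P2
    size_class: small
    zones:
      windward:
        <<: *zone_defaults
        trait_means: *means_windward
        trait_cvs: *cvs_windward
      core:
        <<: *zone_defaults
        trait_means: *means_core
        trait_cvs: *cvs_core
      leeward:
        <<: *zone_defaults
        trait_means: *means_core
        trait_cvs: *cvs_core
  - patch_id: P3
    size_class: large
    zones:
      windward:
        <<: *zone_defaults
        trait_means: *means_windward
        trait_cvs: *cvs_windward
        correlation: *corr_windward
      core:
        <<: *zone_defaults
        trait_means: *means_core
        trait_cvs: *cvs_core
        correlation: *corr_core
      leeward:
        <<: *zone_defaults
        trait_means: *means_leeward
        trait_cvs: *cvs_leeward
        correlation: *corr_leeward
  - patch_id: P4
    size_class: large
    zones:
      windward:
        <<: *zone_defaults
        trait_means: *means_windward
        trait_cvs: *cvs_windward
        correlation: *corr_windward
      core:
        <<: *zone_defaults
        trait_means: *means_core
        trait_cvs: *cvs_core
        correlation: *corr_core
      leeward:
        <<: *zone_defaults
        trait_means: *means_leeward
        trait_cvs: *cvs_leeward
        correlation: *corr_leeward
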
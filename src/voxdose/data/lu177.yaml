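# Lu-177 decay and interaction data for voxel dose computation.
#
# Sources:
#   half_life_h, beta_endpoint_kev, beta_range_mm: standard Lu-177 decay
#     characteristics (6.7 d physical half-life, 498 keV maximal beta
#     energy, ~2 mm maximal particle range in soft tissue).
#   beta_spectrum: three-branch approximation of the Lu-177 beta decay
#     (branch mean energies and intensities after ENSDF/ICRP-107 rounding);
#     overall mean beta energy ~134 keV.
#   photon_lines: principal gamma emissions (ENSDF rounding).
#   mass_attenuation_water: photoelectric column is a power-law fit
#     (~E^-3.05) anchored to NIST XCOM water near 100 keV; incoherent
#     column is the free-electron Klein-Nishina cross section times the
#     electron density of water (3.3428e23 e/g).  Coherent scattering and
#     bound-electron corrections are intentionally omitted (documented
#     engine approximation).
#   csda_range_water: electron CSDA ranges in water (NIST ESTAR rounding),
#     in mm at unit density.
name: Lu-177
physical_half_life_h: 160.8        # 6.7 d
beta_endpoint_kev: 498.0
beta_range_mm: 2.0
beta_spectrum:                     # [mean energy keV, branch probability]
  - [47.0, 0.116]
  - [111.7, 0.090]
  - [149.4, 0.794]
photon_lines:                      # [energy keV, yield per decay]
  - [112.95, 0.0617]
  - [208.37, 0.1036]
  - [249.67, 0.0021]
  - [321.32, 0.0022]
mass_attenuation_water:            # [energy keV, photoelectric, incoherent] cm^2/g
  - [20, 3.7391e-01, 2.0658e-01]
  - [30, 1.0856e-01, 1.9973e-01]
  - [40, 4.5147e-02, 1.9346e-01]
  - [50, 2.2859e-02, 1.8770e-01]
  - [60, 1.3108e-02, 1.8239e-01]
  - [80, 5.4511e-03, 1.7292e-01]
  - [100, 2.7600e-03, 1.6472e-01]
  - [150, 8.0137e-04, 1.4829e-01]
  - [200, 3.3325e-04, 1.3588e-01]
  - [300, 9.6759e-05, 1.1815e-01]
  - [400, 4.0237e-05, 1.0586e-01]
  - [500, 2.0373e-05, 9.6663e-02]
  - [600, 1.1683e-05, 8.9419e-02]
csda_range_water:                  # [energy keV, CSDA range mm in water]
  - [10, 0.0025]
  - [20, 0.0086]
  - [30, 0.0176]
  - [50, 0.0432]
  - [70, 0.0785]
  - [100, 0.1431]
  - [150, 0.2817]
  - [200, 0.4487]
  - [300, 0.8421]
  - [400, 1.2850]
  - [500, 1.7584]
  - [600, 2.2500]
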
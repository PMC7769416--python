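# Default excess-absolute-risk coefficients, editable.
#
# EAR0 is excess cases per 10^4 person-years per Gy at attained age 70,
# for exposure at age 30 or 50, with 90% confidence intervals, consistent
# with the Japanese atomic-bomb-survivor solid-cancer incidence analyses
# (Preston et al., Radiat Res 168:1-64, 2007).  These are convenience
# defaults for the shipped pipeline; analyses with other populations
# should substitute their own table.
attained_age: 70
coefficients:
  - {organ: breast,        exposure_age: 30, ear0_per_10k_py_gy: 9.206, ci90: [6.787, 11.986], source: LSS incidence}
  - {organ: breast,        exposure_age: 50, ear0_per_10k_py_gy: 3.682, ci90: [2.101, 5.885],  source: LSS incidence}
  - {organ: stomach,       exposure_age: 30, ear0_per_10k_py_gy: 9.498, ci90: [6.104, 13.996], source: LSS incidence}
  - {organ: stomach,       exposure_age: 50, ear0_per_10k_py_gy: 9.197, ci90: [4.197, 15.984], source: LSS incidence}
  - {organ: lung,          exposure_age: 30, ear0_per_10k_py_gy: 7.512, ci90: [5.110, 10.000], source: LSS incidence}
  - {organ: lung,          exposure_age: 50, ear0_per_10k_py_gy: 7.811, ci90: [4.606, 12.047], source: LSS incidence}
  - {organ: thyroid,       exposure_age: 30, ear0_per_10k_py_gy: 1.205, ci90: [0.501, 2.205],  source: LSS incidence}
  - {organ: thyroid,       exposure_age: 50, ear0_per_10k_py_gy: 0.401, ci90: [0.000, 1.299],  source: LSS incidence}
  - {organ: colon,         exposure_age: 30, ear0_per_10k_py_gy: 8.000, ci90: [4.396, 12.000], source: LSS incidence}
  - {organ: colon,         exposure_age: 50, ear0_per_10k_py_gy: 1.598, ci90: [0.300, 3.906],  source: LSS incidence}
  - {organ: liver,         exposure_age: 30, ear0_per_10k_py_gy: 4.292, ci90: [0.000, 7.192],  source: LSS incidence}
  - {organ: liver,         exposure_age: 50, ear0_per_10k_py_gy: 2.603, ci90: [0.500, 6.393],  source: LSS incidence}
  - {organ: esophagus,     exposure_age: 30, ear0_per_10k_py_gy: 0.577, ci90: [0.180, 1.100],  source: LSS incidence}
  - {organ: oral cavity,   exposure_age: 30, ear0_per_10k_py_gy: 0.561, ci90: [0.200, 1.201],  source: LSS incidence}
  - {organ: skin,          exposure_age: 30, ear0_per_10k_py_gy: 0.350, ci90: [0.030, 1.103],  source: LSS incidence}
  - {organ: skin,          exposure_age: 50, ear0_per_10k_py_gy: 0.364,                        source: LSS incidence}
  - {organ: pancreas,      exposure_age: 30, ear0_per_10k_py_gy: 0.460, ci90: [0.000, 1.503],  source: LSS incidence}
  - {organ: cns,           exposure_age: 30, ear0_per_10k_py_gy: 0.508, ci90: [0.169, 0.946],  source: LSS incidence}
  - {organ: bladder,       exposure_age: 30, ear0_per_10k_py_gy: 3.650, ci90: [1.250, 6.150],  source: LSS incidence}
  - {organ: bladder,       exposure_age: 50, ear0_per_10k_py_gy: 2.400, ci90: [0.550, 5.100],  source: LSS incidence}
  - {organ: kidney,        exposure_age: 30, ear0_per_10k_py_gy: 0.080, ci90: [0.000, 0.437],  source: LSS incidence}
  - {organ: ovary,         exposure_age: 30, ear0_per_10k_py_gy: 0.533, ci90: [0.033, 1.233],  source: LSS incidence}
  - {organ: uterus,        exposure_age: 30, ear0_per_10k_py_gy: 0.700, ci90: [0.000, 2.350],  source: LSS incidence}
  - {organ: gall bladder,  exposure_age: 30, ear0_per_10k_py_gy: 0.000, ci90: [0.000, 0.510],  source: LSS incidence}
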
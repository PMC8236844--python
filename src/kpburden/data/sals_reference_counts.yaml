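# Worked-example reference data: per-gene qualifying-variant counts reported
# from a 614-case sporadic ALS whole-genome screen of this 18-gene panel
# against three control resources (gnomAD non-Finnish European non-neuro
# subset, AOGC, MGRB), with the printed percentage columns, and the printed
# consensus-score / tool-count pairs of the nine novel variants from the same
# screen. A null count marks a dataset with insufficient data for that gene.
cohorts:
  SALS: 614
  nNFE: 51592
  AOGC: 967
  MGRB: 1144
genes:
  AFMID: {counts: {SALS: 8, nNFE: 155, AOGC: 9, MGRB: 11},
          pct: {SALS: 1.30, nNFE: 0.30, AOGC: 0.93, MGRB: 0.96}}
  HAAO:  {counts: {SALS: 7, nNFE: 97, AOGC: 3, MGRB: 18},
          pct: {SALS: 1.14, nNFE: 0.19, AOGC: 0.31, MGRB: 1.57}}
  KYAT1: {counts: {SALS: 11, nNFE: 173, AOGC: 8, MGRB: 15},
          pct: {SALS: 1.79, nNFE: 0.34, AOGC: 0.83, MGRB: 1.31}}
  TPH1:  {counts: {SALS: 8, nNFE: 121, AOGC: 8, MGRB: 12},
          pct: {SALS: 1.30, nNFE: 0.23, AOGC: 0.83, MGRB: 1.05}}
  WARS:  {counts: {SALS: 8, nNFE: 146, AOGC: 6, MGRB: 19},
          pct: {SALS: 1.30, nNFE: 0.28, AOGC: 0.62, MGRB: 1.66}}
  AADAT: {counts: {SALS: 1, nNFE: 80, AOGC: 2, MGRB: 3},
          pct: {SALS: 0.16, nNFE: 0.16, AOGC: 0.21, MGRB: 0.26}}
  ACMSD: {counts: {SALS: 2, nNFE: 110, AOGC: 1, MGRB: 4},
          pct: {SALS: 0.33, nNFE: 0.21, AOGC: 0.10, MGRB: 0.35}}
  DDC:   {counts: {SALS: 4, nNFE: 171, AOGC: 5, MGRB: 6},
          pct: {SALS: 0.65, nNFE: 0.33, AOGC: 0.52, MGRB: 0.52}}
  GOT2:  {counts: {SALS: 1, nNFE: 111, AOGC: 4, MGRB: 4},
          pct: {SALS: 0.16, nNFE: 0.22, AOGC: 0.41, MGRB: 0.35}}
  IDO1:  {counts: {SALS: 6, nNFE: 152, AOGC: 4, MGRB: 4},
          pct: {SALS: 0.98, nNFE: 0.29, AOGC: 0.41, MGRB: 0.35}}
  IDO2:  {counts: {SALS: 3, nNFE: 129, AOGC: 7, MGRB: 8},
          pct: {SALS: 0.49, nNFE: 0.25, AOGC: 0.72, MGRB: 0.70}}
  KMO:   {counts: {SALS: 7, nNFE: 126, AOGC: 6, MGRB: 10},
          pct: {SALS: 1.14, nNFE: 0.24, AOGC: 0.62, MGRB: 0.87}}
  KYAT3: {counts: {SALS: 5, nNFE: 129, AOGC: 2, MGRB: 11},
          pct: {SALS: 0.81, nNFE: 0.25, AOGC: 0.21, MGRB: 0.96}}
  KYNU:  {counts: {SALS: 2, nNFE: 170, AOGC: 7, MGRB: 7},
          pct: {SALS: 0.33, nNFE: 0.33, AOGC: 0.72, MGRB: 0.61}}
  MAOA:  {counts: {SALS: 3, nNFE: 60, AOGC: 3, MGRB: 1},
          pct: {SALS: 0.49, nNFE: 0.12, AOGC: 0.31, MGRB: 0.09}}
  QPRT:  {counts: {SALS: 2, nNFE: 90, AOGC: null, MGRB: 17},
          pct: {SALS: 0.33, nNFE: 0.17, AOGC: null, MGRB: 1.49}}
  TDO2:  {counts: {SALS: 4, nNFE: 138, AOGC: 4, MGRB: 12},
          pct: {SALS: 0.65, nNFE: 0.27, AOGC: 0.41, MGRB: 1.05}}
  TPH2:  {counts: {SALS: 2, nNFE: 134, AOGC: 6, MGRB: 1},
          pct: {SALS: 0.33, nNFE: 0.26, AOGC: 0.62, MGRB: 0.09}}
# (consensus score, number of tools with results) pairs of the nine reported
# novel protein-altering variants
novel_scores:
  - [0.92, 12]
  - [1, 4]
  - [1, 4]
  - [0.83, 12]
  - [0.83, 12]
  - [0.58, 12]
  - [0.5, 12]
  - [0.33, 12]
  - [0.25, 12]
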
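{
 "centralities": {
  "betweenness": {
   "A1": 0.13333333333333333,
   "A2": 0.0,
   "A3": 0.0,
   "A4": 0.0,
   "A5": 0.0,
   "B1": 0.0,
   "B2": 0.0,
   "B3": 0.0,
   "C1": 0.0,
   "C2": 0.0,
   "D1": 0.0
  },
  "closeness": {
   "A1": 1.0,
   "A2": 0.5714285714285714,
   "A3": 0.5714285714285714,
   "A4": 0.5714285714285714,
   "A5": 0.5714285714285714,
   "B1": 1.0,
   "B2": 1.0,
   "B3": 1.0,
   "C1": 1.0,
   "C2": 1.0,
   "D1": 0.0
  },
  "degree": {
   "A1": 4.0,
   "A2": 1.0,
   "A3": 1.0,
   "A4": 1.0,
   "A5": 1.0,
   "B1": 2.0,
   "B2": 2.0,
   "B3": 2.0,
   "C1": 1.0,
   "C2": 1.0,
   "D1": 0.0
  },
  "eigenvector": {
   "A1": 1.0,
   "A2": 0.4999999999964593,
   "A3": 0.4999999999964593,
   "A4": 0.4999999999964593,
   "A5": 0.4999999999964593,
   "B1": 1.0,
   "B2": 1.0,
   "B3": 1.0,
   "C1": 1.0,
   "C2": 1.0,
   "D1": 0.0
  },
  "information": {
   "A1": 1.25,
   "A2": 0.7142857142857143,
   "A3": 0.7142857142857143,
   "A4": 0.7142857142857144,
   "A5": 0.7142857142857143,
   "B1": 2.25,
   "B2": 2.25,
   "B3": 2.25,
   "C1": 2.0,
   "C2": 2.0,
   "D1": 0.0
  },
  "lac": {
   "A1": 0.0,
   "A2": 0.0,
   "A3": 0.0,
   "A4": 0.0,
   "A5": 0.0,
   "B1": 1.0,
   "B2": 1.0,
   "B3": 1.0,
   "C1": 0.0,
   "C2": 0.0,
   "D1": 0.0
  },
  "nc": {
   "A1": 0.0,
   "A2": 0.0,
   "A3": 0.0,
   "A4": 0.0,
   "A5": 0.0,
   "B1": 2.0,
   "B2": 2.0,
   "B3": 2.0,
   "C1": 0.0,
   "C2": 0.0,
   "D1": 0.0
  },
  "subgraph": {
   "A1": 3.762195691083632,
   "A2": 1.6905489227709078,
   "A3": 1.690548922770908,
   "A4": 1.6905489227709078,
   "A5": 1.690548922770908,
   "B1": 2.7082716604245127,
   "B2": 2.7082716604245127,
   "B3": 2.7082716604245123,
   "C1": 1.543080634815244,
   "C2": 1.5430806348152437,
   "D1": 1.0
  }
 },
 "fisher_planted_term": {
  "p_greater": 0.0030303030303030303,
  "table": [
   4,
   0,
   0,
   7
  ]
 },
 "markers": {
  "A1": {
   "binding_content": 0.2,
   "disorder_content": 0.4,
   "domain_count": 2,
   "domain_coverage": 1.0,
   "isoform_count": 4,
   "longest_disordered_region": 4,
   "mean_disordered_region": 4.0,
   "surface_fraction": 0.7
  },
  "C1": {
   "disorder_content": 0.0,
   "domain_count": 2,
   "domain_coverage": 0.6666666666666666,
   "isoform_count": 2,
   "surface_fraction": 1.0
  }
 },
 "merged_interaction_counts": {
  "A1": 4,
  "A2": 1,
  "B1": 2,
  "B2": 3
 },
 "quartiles": {
  "Dh": [
   "A1",
   "B2"
  ],
  "Dl": [
   "A2"
  ],
  "P25": 1,
  "P75": 3
 },
 "wang": {
  "BP:X|BP:Y": 0.41176470588235287,
  "MF:A|MF:R": 0.6428571428571429
 }
}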
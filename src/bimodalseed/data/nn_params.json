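{
 "bulge_by_size": [
  3.8,
  2.8,
  3.2,
  3.6,
  4.0,
  4.4,
  4.6,
  4.7,
  4.8,
  4.9
 ],
 "comment": "Simplified pair-strength nearest-neighbor table for intermolecular RNA duplexes. Stack keys are XY/X'Y': X,Y consecutive bases of strand a (5'->3'); X',Y' their partners on strand b (3'->5'). Synthetic, internally consistent table; not the Turner set.",
 "initiation": 4.09,
 "internal_by_total_size": [
  1.7,
  2.3,
  2.7,
  3.2,
  3.5,
  3.8,
  4.0,
  4.2,
  4.35,
  4.5,
  4.65,
  4.8,
  4.9,
  5.0,
  5.1,
  5.2,
  5.3,
  5.4,
  5.5
 ],
 "loop_extension_per_nt": 0.3,
 "max_loop_per_side": 10,
 "stack": {
  "AA/UU": -1.2,
  "AC/UG": -2.2,
  "AG/UC": -2.2,
  "AG/UU": -0.85,
  "AU/UA": -1.2,
  "AU/UG": -0.85,
  "CA/GU": -2.2,
  "CC/GG": -3.2,
  "CG/GC": -3.2,
  "CG/GU": -1.85,
  "CU/GA": -2.2,
  "CU/GG": -1.85,
  "GA/CU": -2.2,
  "GA/UU": -0.85,
  "GC/CG": -3.2,
  "GC/UG": -1.85,
  "GG/CC": -3.2,
  "GG/CU": -1.85,
  "GG/UC": -1.85,
  "GG/UU": -0.5,
  "GU/CA": -2.2,
  "GU/CG": -1.85,
  "GU/UA": -0.85,
  "GU/UG": -0.5,
  "UA/AU": -1.2,
  "UA/GU": -0.85,
  "UC/AG": -2.2,
  "UC/GG": -1.85,
  "UG/AC": -2.2,
  "UG/AU": -0.85,
  "UG/GC": -1.85,
  "UG/GU": -0.5,
  "UU/AA": -1.2,
  "UU/AG": -0.85,
  "UU/GA": -0.85,
  "UU/GG": -0.5
 },
 "version": "bimodalseed-nn-1"
}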
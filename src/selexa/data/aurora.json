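{
 "name": "aurora-synthetic-fixture",
 "comment": "synthetic stand-in reference; layout parameters follow the published pool design",
 "reference": "ATCATGTAAAGATAACTGTCACGTTTTACAGATGAGGAAATTGTTTCAACACAATGGAATAACCCCAGCCCAGGGCAAGGCAGCACTCCGTAAGCGACGGAGCAG",
 "mutagenized_region": [
  1,
  85
 ],
 "primer3": "CTCCGTAAGCGACGGAGCAG",
 "primer_tag5": "TCCACCCATTTATTGGCACG",
 "mu": 0.21,
 "pairs": [
  [
   11,
   47
  ],
  [
   12,
   46
  ],
  [
   17,
   40
  ],
  [
   26,
   30
  ]
 ],
 "conserved_blocks": [
  [
   1,
   10
  ],
  [
   43,
   79
  ]
 ],
 "mismatch_penalty": 0.05,
 "capture": 0.5,
 "n_rounds": 5
}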
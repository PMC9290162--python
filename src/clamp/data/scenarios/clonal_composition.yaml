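# Clonal-composition showcase: K247R occurs only together with T315I, never
# in isolation, while L273M and T315I live in distinct molecules.
isoform_id: e14a2
n_reads: 10000
clones:
  - {mutations: [L273M], fraction: 0.56}
  - {mutations: [T315I], fraction: 0.41}
  - {mutations: [T315I, K247R], fraction: 0.03}
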
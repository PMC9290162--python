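# Two resistance mutations on separate clones (VAFs 84.9 / 14.4 %).
isoform_id: e14a2
n_reads: 10000
clones:
  - {mutations: [F359I], fraction: 0.849}
  - {mutations: [T315I], fraction: 0.144}
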
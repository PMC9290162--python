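# Validation-cohort scenario: dominant gatekeeper clone with two low-level
# secondary mutations nested on the same backbone (VAFs 96.8 / 2.1 / 1.2 %).
isoform_id: e14a2
n_reads: 10000
clones:
  - {mutations: [T315I], fraction: 0.935}
  - {mutations: [T315I, F359C], fraction: 0.021}
  - {mutations: [T315I, H396R], fraction: 0.012}
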
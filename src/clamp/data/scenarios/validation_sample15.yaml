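# Two major clones in distinct molecules plus a rare mutation that occurs
# only on the gatekeeper backbone (VAFs 58.1 / 41.7 / 2.8 %).
isoform_id: e14a2
n_reads: 10000
clones:
  - {mutations: [L273M], fraction: 0.581}
  - {mutations: [T315I], fraction: 0.389}
  - {mutations: [T315I, K247R], fraction: 0.028}
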
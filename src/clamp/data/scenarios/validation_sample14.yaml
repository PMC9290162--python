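# Five co-detected mutations on disjoint clones (VAFs 45.7 / 23.9 / 12.5 /
# 12.4 / 4.8 %); F359I and F359V share a codon and must stay distinguishable.
isoform_id: e14a2
n_reads: 10000
clones:
  - {mutations: [T315I], fraction: 0.457}
  - {mutations: [F359I], fraction: 0.239}
  - {mutations: [E255K], fraction: 0.125}
  - {mutations: [H396R], fraction: 0.124}
  - {mutations: [F359V], fraction: 0.048}
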
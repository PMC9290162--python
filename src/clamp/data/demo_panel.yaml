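# Demo amplicon panel for BCR-ABL1 kinase-domain TKI-resistance screening.
#
# Schema (one YAML/JSON mapping):
#   forward_primer          DNA, >=10 bases, as synthesized 5'->3'
#   reverse_primer          DNA, >=10 bases, as synthesized 5'->3' on the
#                           opposite strand
#   max_primer_mismatches   int >= 0 (default 2)
#   positive_cutoff         fraction in (0,1), default 0.005; VAF >= cutoff
#                           is a positive call (inclusive)
#   clinical_cutoff         fraction in (0,1), default 0.01; VAF strictly
#                           above is clinically reportable
#   min_coverage            int, default 100: per-position QC floor
#   min_alt_reads           int, default 3: absolute floor for de novo calls
#   isoforms                list; each entry needs isoform_id, cds_start
#                           (1-based first base of the first complete codon),
#                           codon_offset (protein number of that codon), and
#                           either an inline `sequence` or a `fasta` path
#                           relative to this file; `description` is free text
#   known_mutations         list of amino-acid labels like T315I
#
# The isoform sequences below are SYNTHETIC stand-ins, engineered so that every
# panel mutation's reference codon is present at its ABL1-numbered position and
# each alternate amino acid is reachable by a single nucleotide substitution.
# They are NOT the true BCR-ABL1 transcript; a real deployment supplies its own
# reference FASTA plus (cds_start, codon_offset) metadata.
forward_primer: CGGTCGGTATCCCTTCCTGTAT
reverse_primer: ACGATAACTTTACCTATATCGA
max_primer_mismatches: 2
positive_cutoff: 0.005
clinical_cutoff: 0.01
min_coverage: 100
min_alt_reads: 3
isoforms:
  - isoform_id: e14a2
    description: synthetic long isoform (dominant form; carries the extra 75-nt 5' block)
    cds_start: 91
    codon_offset: 240
    sequence: TCTATTTGGACAACCGAAAGCCCAAAGAGCGACGAGTGGTAAATACGTAAGCACTGGAATCTTTTAGCGCCCCAGCCAAAATAAGGTGTGTTGAAACATCCAATGCTAGCTAAATTGTCTATTATCCGTTACGGTGAATCTTATGTAGTGCTTTATAAGGCAGACGGAGTCCGCAGGTTGGCACCAACCCTGCTCCACGACGTTAACGCGTACTCTCTATCACGCAATGATTTACTCGTAACTATCCCGATGAACGGGTTCGAGCTGTGGTTCTCACGCCCTGTTCCAGTCAATGTCTGCTGCGCACATGGTAGCACTAGGGCTGCCAACAGGTCGTCCAGCAGCGGAGACCCATATTTATTTTTACAGCGTAGAGTGTCCTCACAACGCAGGGCGTCCGGCCTCGATCTGATCAGGCTAAGCCCACCTACGCCTCAAAGCATTGGCTTCGTGGATGTTACTAGGTGCTATGTGAGTAGCTTAGAATGGAATATAAGCATCGTCCCTCTCCACCTGAAGAAGGATTTCTTGCTGTCGGTAAGCCTATTCTTTGAAACGCACGTTGGCATACAGCCGTGGTCACGACACGTTCCAACTTGTCCTACGCTGGGGCCTGGTAACGCCGGGGATATGCATTGGGTTAGTGTGCATATCTTTCCATTCGTAGTGCGAACTACTCGCATGGTCCAAGTAGACGAGTTCGGGCAGCTCGATGGACAGGAAGAACAGAGCGCGCTACCGTGCATATTGGCGCGCGCTCTCACGGGCTGCAACACCCCGTGGATCATGCCTGGTCAGAGTCACTGCCTG
  - isoform_id: e13a2
    description: synthetic short isoform (75-nt 5' block absent)
    cds_start: 16
    codon_offset: 240
    sequence: TCTATTTAAGGTGTGTTGAAACATCCAATGCTAGCTAAATTGTCTATTATCCGTTACGGTGAATCTTATGTAGTGCTTTATAAGGCAGACGGAGTCCGCAGGTTGGCACCAACCCTGCTCCACGACGTTAACGCGTACTCTCTATCACGCAATGATTTACTCGTAACTATCCCGATGAACGGGTTCGAGCTGTGGTTCTCACGCCCTGTTCCAGTCAATGTCTGCTGCGCACATGGTAGCACTAGGGCTGCCAACAGGTCGTCCAGCAGCGGAGACCCATATTTATTTTTACAGCGTAGAGTGTCCTCACAACGCAGGGCGTCCGGCCTCGATCTGATCAGGCTAAGCCCACCTACGCCTCAAAGCATTGGCTTCGTGGATGTTACTAGGTGCTATGTGAGTAGCTTAGAATGGAATATAAGCATCGTCCCTCTCCACCTGAAGAAGGATTTCTTGCTGTCGGTAAGCCTATTCTTTGAAACGCACGTTGGCATACAGCCGTGGTCACGACACGTTCCAACTTGTCCTACGCTGGGGCCTGGTAACGCCGGGGATATGCATTGGGTTAGTGTGCATATCTTTCCATTCGTAGTGCGAACTACTCGCATGGTCCAAGTAGACGAGTTCGGGCAGCTCGATGGACAGGAAGAACAGAGCGCGCTACCGTGCATATTGGCGCGCGCTCTCACGGGCTGCAACACCCCGTGGATCATGCCTGGTCAGAGTCACTGCCTG
known_mutations: [M244V, K247R, Y253H, E255K, E255V, L273M, D276G, L298V, T315I, F359C, F359I, F359V, H396R, E450G, M472I]
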
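# Sequence constraints for the heterodimerization task (16 entity
# positions: odd = chain A, even = chain B).
#
# Homodimer penalty: each odd/even pair carrying the same amino acid counts
# toward the identity total; up to 6 identical pairs are free, each further
# one costs 5 REU.
IDENTITY_PENALTY free 6 step 5 pairs 1:2 3:4 5:6 7:8 9:10 11:12 13:14 15:16
# Minimal-mutation penalty: each chain may carry 5 mutations from wild type
# for free; each further mutation costs 1 REU.
MUTATION_PENALTY free 5 step 1 positions 1 3 5 7 9 11 13 15 wildtype FALAGLVW
MUTATION_PENALTY free 5 step 1 positions 2 4 6 8 10 12 14 16 wildtype FALAGLVW
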
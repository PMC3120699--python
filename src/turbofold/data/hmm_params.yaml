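# Default pairwise alignment HMM parameters -- version 1.
#
# Three-state pair HMM over {ALN, INS1, INS2} with affine-gap semantics:
# ALN emits an aligned nucleotide pair, INS1 emits a nucleotide of the first
# sequence only, INS2 of the second only.  A silent begin state enters the
# three states with the stationary distribution of the transition matrix;
# termination is allowed from any state.
#
# These are documented defaults (match-biased emissions, gap-open ~ 0.03,
# gap-extend ~ 0.3), not values trained on alignment databases; any file
# with the same schema may be substituted.

transition:          # rows/cols ordered ALN, INS1, INS2; rows sum to 1
  ALN:  [0.94, 0.03, 0.03]
  INS1: [0.69, 0.30, 0.01]
  INS2: [0.69, 0.01, 0.30]

match_emission:      # joint P(a, b); rows/cols ordered A, C, G, U
  - [0.16, 0.03, 0.03, 0.03]
  - [0.03, 0.16, 0.03, 0.03]
  - [0.03, 0.03, 0.16, 0.03]
  - [0.03, 0.03, 0.03, 0.16]

insert_emission: [0.25, 0.25, 0.25, 0.25]
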
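# Simplified nearest-neighbor free-energy parameters for RNA folding.
# Version 1 -- shipped defaults of the turbofold package.
#
# Model: Watson-Crick + GU wobble stacks, length-dependent hairpin / bulge /
# internal loop penalties, a linear multibranch-loop model (a + b per branch
# + c per unpaired nucleotide), and a terminal AU/GU helix-end penalty
# applied once per non-stacked side of an AU/UA/GU/UG pair.  No dangling
# ends, coaxial stacking, special hairpins, or loop-asymmetry terms.
#
# Loop penalties beyond the largest tabulated length L are extrapolated as
#     G(n) = G(L) + lxc * ln(n / L)          [kcal/mol]
# with lxc = 1.75 * RT at 310.15 K.
#
# All energies in kcal/mol at 310.15 K.  Stack keys "XY/WZ" denote the
# closing pair (x_i, x_j) = XY stacked on the enclosed pair
# (x_{i+1}, x_{j-1}) = WZ; the table satisfies the reverse-complement
# symmetry  G(XY/WZ) = G(ZW/YX).

RT: 0.61633
temperature: 310.15
min_hairpin: 3
terminal_AU: 0.5
lxc: 1.07858

multibranch:
  a: 3.4
  b: 0.4
  c: 0.1

stack:
  AU/AU: -0.9
  AU/UA: -1.1
  AU/GC: -2.1
  AU/CG: -2.2
  AU/GU: -0.6
  AU/UG: -1.4
  UA/AU: -1.3
  UA/UA: -0.9
  UA/GC: -2.1
  UA/CG: -2.4
  UA/GU: -1.0
  UA/UG: -1.3
  GC/AU: -2.4
  GC/UA: -2.2
  GC/GC: -3.3
  GC/CG: -3.4
  GC/GU: -1.5
  GC/UG: -2.5
  CG/AU: -2.1
  CG/UA: -2.1
  CG/GC: -2.4
  CG/CG: -3.3
  CG/GU: -1.4
  CG/UG: -2.1
  GU/AU: -1.3
  GU/UA: -1.4
  GU/GC: -2.1
  GU/CG: -2.5
  GU/GU: -0.5
  GU/UG: 0.5
  UG/AU: -1.0
  UG/UA: -0.6
  UG/GC: -1.4
  UG/CG: -1.5
  UG/GU: -0.6
  UG/UG: -0.5

hairpin_by_len:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.8
  7: 5.9
  8: 6.0
  9: 6.1

bulge_by_len:
  1: 3.8
  2: 2.8
  3: 3.2
  4: 3.6
  5: 4.0
  6: 4.4

internal_by_len:
  2: 1.5
  3: 1.8
  4: 2.0
  5: 2.2
  6: 2.5
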
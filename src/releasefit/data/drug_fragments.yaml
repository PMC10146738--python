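# Group-fragment multisets for the nine studied benzoic-acid-derived drugs.
#
# Fragmentation convention: the para-(or ortho/meta-)disubstituted benzene
# ring is one "phenylene" fragment; methoxy is "-O-" + "-CH3"; esters are
# "-COO-" plus the alkyl chain.  Positional isomers share one multiset by
# construction (group-contribution methods are blind to substitution
# position), so 2-MBA, 3-MBA and 4-MBA are identical here.
#
# PHBA  p-hydroxybenzoic acid      MPDB  methyl p-hydroxybenzoate
# PABA  p-aminobenzoic acid        MPAB  methyl p-aminobenzoate
# EPAB  ethyl p-aminobenzoate      BPAB  n-butyl p-aminobenzoate
# 2/3/4-MBA  o/m/p-methoxybenzoic acid
version: 1
molecules:
  PHBA:  {"phenylene": 1, "-OH": 1, "-COOH": 1}
  MPDB:  {"phenylene": 1, "-OH": 1, "-COO-": 1, "-CH3": 1}
  PABA:  {"phenylene": 1, "-NH2": 1, "-COOH": 1}
  MPAB:  {"phenylene": 1, "-NH2": 1, "-COO-": 1, "-CH3": 1}
  EPAB:  {"phenylene": 1, "-NH2": 1, "-COO-": 1, "-CH3": 1, "-CH2-": 1}
  BPAB:  {"phenylene": 1, "-NH2": 1, "-COO-": 1, "-CH3": 1, "-CH2-": 3}
  2-MBA: {"phenylene": 1, "-COOH": 1, "-O-": 1, "-CH3": 1}
  3-MBA: {"phenylene": 1, "-COOH": 1, "-O-": 1, "-CH3": 1}
  4-MBA: {"phenylene": 1, "-COOH": 1, "-O-": 1, "-CH3": 1}
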
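# Synthetic reconstruction of the alpha1-syntrophin-derived PDZ contact map.
# The published analysis reports 38 (domain position, peptide position)
# pairs within 5 A, spanning 16 aligned binding-site columns and all five
# C-terminal peptide positions, but does not list the pairs themselves.
# This file is a stand-in with the same structural constants: 38 unique
# pairs, all 16 domain positions represented, all 5 peptide positions
# represented, with contact density highest around p0 (the hydrophobic
# pocket between beta2 and alpha2) and p-2.
# Format: <domain position 1..16> <peptide position p-4..p0>
1 p0
2 p0
2 p-1
3 p0
3 p-1
3 p-2
4 p0
4 p-1
4 p-2
5 p0
5 p-1
6 p-1
6 p-2
6 p-3
7 p-2
7 p-3
8 p-2
8 p-3
9 p-2
9 p-3
9 p-4
10 p-3
10 p-4
11 p-3
11 p-4
12 p-3
12 p-4
13 p0
13 p-1
13 p-2
14 p0
14 p-1
14 p-2
15 p0
15 p-2
16 p0
16 p-2
16 p-4
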
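"""Merge two tree collections directly on their compressed documents.

Two runs of a phylogenetic search are compressed separately; union,
intersection and set difference of the collections (as sets of unique
trees, branch lengths included) are computed on the TRZ documents
without rebuilding any tree structure, and each result is again a TRZ
document.
"""

from treezip import apply_setop, compress, read_newick_file

FILE1 = """\
(((A : 0.12, B : 0.13) : 0.14, C : 0.15) : 0.16, (D : 0.17, (E : 0.18, F : 0.19) : 0.20) : 0.21);
(((A : 0.11, B : 0.34) : 0.29, D : 0.23) : 0.22, (C : 0.24, (E : 0.25, F : 0.26) : 0.27) : 0.28);
(((A : 0.29, B : 0.11) : 0.31, E : 0.33) : 0.15, (D : 0.38, (C : 0.36, F : 0.37) : 0.32) : 0.31);
"""
# tree 1 below is the same tree as tree 1 above, written differently
FILE2 = """\
(((E : 0.18, F : 0.19) : 0.20, D : 0.17) : 0.21, (C : 0.15, (A : 0.12, B : 0.13) : 0.14) : 0.16);
(((A : 0.34, B : 0.23) : 0.21, C : 0.53) : 0.24, (F : 0.41, (E : 0.13, D : 0.51) : 0.21) : 0.33);
(((A : 0.12, B : 0.43) : 0.21, C : 0.06) : 0.20, (E : 0.04, (D : 0.28, F : 0.33) : 0.02) : 0.41);
"""

trees1, taxa = read_newick_file(FILE1)
trees2, _ = read_newick_file(FILE2)
a, b = compress(trees1, taxa), compress(trees2, taxa)

for op in ("union", "intersection", "difference"):
    result = apply_setop(a, b, op)
    print(f"{op:12s} -> {result.header.t} unique tree(s)")
print("(3 + 3 input trees, one shared: 5 in the union, 1 in the "
      "intersection, 2 only in the first file)")
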
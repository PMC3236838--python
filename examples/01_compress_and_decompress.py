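"""Compress a small weighted Newick collection and get every tree back.

Three 6-taxon trees share most of their bipartitions, so the TRZ
document stores each shared clade once with the list of trees that
contain it.  Decompression rebuilds the trees in file order; the Newick
strings that come out may order children differently, but each line is
the same tree, which the canonical key comparison demonstrates.
"""

from treezip import (
    canonical_topology_key,
    compress,
    decompress_all,
    read_newick_file,
    write_newick,
    write_trz,
)

NEWICK = """\
(((A : 0.12, B : 0.13) : 0.14, C : 0.15) : 0.16, (D : 0.17, (E : 0.18, F : 0.19) : 0.20) : 0.21);
(((A : 0.11, B : 0.34) : 0.29, D : 0.23) : 0.22, (C : 0.24, (E : 0.25, F : 0.26) : 0.27) : 0.28);
(((A : 0.29, B : 0.11) : 0.31, E : 0.33) : 0.15, (D : 0.38, (C : 0.36, F : 0.37) : 0.32) : 0.31);
"""

trees, taxa = read_newick_file(NEWICK)
doc = compress(trees, taxa)
print(f"t={doc.header.t} trees, u={doc.header.u} unique, "
      f"B={doc.header.n_bipartitions} unique bipartitions")

blob = write_trz(doc)
print(f"Newick {len(NEWICK.encode())} bytes -> TRZ {len(blob)} bytes")
print("--- TRZ document ---")
print(blob.decode("latin-1"), end="")
print("--------------------")

for original, rebuilt in zip(trees, decompress_all(doc)):
    same = canonical_topology_key(original) == canonical_topology_key(rebuilt)
    print(f"rebuilt {write_newick(rebuilt, canonical=True, mantissa_digits=6)}"
          f"   same tree as input: {same}")
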
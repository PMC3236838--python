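"""Filter a compressed collection without decompressing it in full.

A Bayesian-style sample repeats topologies; the TRZ document knows the
unique trees and every bipartition's occurrence count, so the unique
subset and the strict / majority-rule consensus trees come straight out
of the compressed form.
"""

from treezip import (
    CollectionSpec,
    compress,
    consensus,
    decompress_unique,
    random_collection,
    read_newick_file,
    write_newick,
)

spec = CollectionSpec(n=8, t=30, perturbation_rate=0.3, dup_rate=0.4, seed=42)
trees, taxa = read_newick_file(random_collection(spec))
doc = compress(trees, taxa)

print(f"collection: t={doc.header.t} sampled trees, u={doc.header.u} unique topologies")
print(f"unique trees extracted: {len(decompress_unique(doc))}")

strict = consensus(doc, "strict")
majority = consensus(doc, "majority")
print("strict consensus   (clades in every tree):   ",
      write_newick(strict, canonical=True))
print("majority consensus (clades in > half of them):",
      write_newick(majority, canonical=True))
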
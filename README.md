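# treezip

Semantic compression for collections of phylogenetic trees.

Phylogenetic searches (Bayesian MCMC with MrBayes-style samplers,
parsimony searches) return tens to hundreds of thousands of candidate
trees over one taxon set, stored as Newick files that easily reach
hundreds of megabytes.  Most of that bulk is redundant: the trees share
the vast majority of their evolutionary relationships.  `treezip`
compresses such a collection by storing each relationship — each
*bipartition*, the set of taxa below an edge — exactly once, together
with the list of trees that contain it and their branch lengths.  The
result is the plain-text **TRZ** format, which is not just smaller but
still *operable*: unique trees, strict and majority-rule consensus
trees, and union / intersection / set difference of two collections are
all computed directly on the compressed documents.

## The model

For a rooted tree on `n` lexicographically ordered taxa, every non-root
node defines a clade encoded as an `n`-bit bitstring `B = (b_0 … b_(n-1))`
(`b_i = 1` iff taxon `i` is below the edge); a rooted binary tree
carries `2(n-1)` of them.  Two universal hash functions organise the
clades of all `t` trees into one table:

    h1(B) = (Σ_i b_i · r_i) mod m1        (bucket index)
    h2(B) = (Σ_i b_i · s_i) mod m2        (short bipartition id, BID)

with seeded random vectors `R`, `S` and primes `m1`, `m2`.  Record
identity is always decided on the full bitstring, so hash collisions
cannot corrupt output.  Identical trees (topology, and branch lengths at
a fixed mantissa precision) are stored once; duplicates are recorded as
a position map.  A TRZ line per unique bipartition then holds:

* the bitstring, run-length encoded (`110000` → `K2L4`);
* the smaller of the tree-id set Γ and its complement Γ̄ (sign `+`/`-`),
  delta- and run-length encoded with `A–J` first digits;
* the branch lengths, two mantissa digits per byte via a `+33` offset,
  with the (rare) non-zero integral parts stored as explicit exceptions.

Lines are sorted canonically (decreasing set-bit count, ties by
decreasing bitstring text), so collections whose trees are identical
produce **byte-identical** TRZ files no matter how their `O(2^(n-1))`
equivalent Newick strings were written.  Decompression refines a star
tree per unique tree: clades arrive largest first and each one bundles
the current children it contains under a new internal node.  Consensus
trees keep the clades occurring in all (`strict`) or more than half
(`majority`) of the `t` trees; set operations compare whole-tree clade
signatures across two documents.

## A worked example

`examples/01_compress_and_decompress.py` compresses three weighted
6-taxon trees and prints:

```
t=3 trees, u=3 unique, B=15 unique bipartitions
--- TRZ document ---
A B C D E F
3
15
U 3 W 1 K 6
K3L3 +A 1!!
K2L1K1L2 +B 7!!
...
K2L4 - /!!>!!@!!
...
```

The header lists the taxa, `t=3` trees, `15` bipartitions, `u=3` unique
trees, the weighted flag and 6 mantissa digits.  `K2L4 -` is the clade
`{A,B}` (bitstring `110000`): its `-` sign with an empty id payload says
*every* tree contains it, and the three byte-pairs after it are the three
branch lengths.  Decompression returns all three trees, in order, equal
to the inputs at mantissa precision.

The other examples show filtering and consensus from the compressed
form (`02`), set operations on two collections — 3 + 3 trees with one
shared tree give union 5, intersection 1, difference 2 (`03`) — and
byte-identical TRZ output when 100 % of the Newick strings are rewritten
into random equivalent forms (`04`).

A thin CLI wraps the same library:

```
treezip compress  trees.nwk trees.trz
treezip decompress trees.trz out.nwk --mode majority
treezip setop a.trz b.trz out.trz --op union
treezip generate -n 20 -t 100 --seed 7 sample.nwk
```

## Format notes

The TRZ dialect written here (separators, the `M` run-count marker, the
self-describing fourth header line, `D` duplicate lines, `!` integral
exceptions) is fixed and documented in `treezip/trz_codec.py`; it makes
no claim of byte compatibility with other TreeZip implementations.
Pairing the output with a general-purpose compressor (gzip/7zip) is
deliberately out of scope — TRZ files are ordinary text and can be piped
into one.
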
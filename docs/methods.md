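# Methods

## Scope and data model

`treezip` operates on collections of rooted trees over a single taxon
set, read from Newick files with one tree per line.  Trees are taken
exactly as written: the rooting of the string is authoritative, children
keep their input order, and no unrooted normalisation or re-rooting is
performed.  Consequently a clade and its complement (e.g. `111000` and
`000111`) are distinct entries, and a rooted binary tree on `n` taxa
contributes `2(n-1)` clades — one per non-root node, leaves included.
Multifurcating trees are supported (fewer clades per tree); a collection
must be uniformly weighted or uniformly unweighted.

Branch lengths are parsed into `decimal.Decimal` (scientific notation is
converted to fixed decimal) and quantized to a fixed, even number of
fractional digits `k` (default 6, recorded in the TRZ header) with
round-half-away-from-zero.  Compression is lossless *at that precision*:
inputs with more digits are rounded by contract.  Negative branch
lengths are rejected at encoding time; integral parts must be < 10^9.

## Tree identity

Two trees are "the same" iff their clade sets are equal — including
quantized branch lengths in weighted mode.  The weight-inclusive rule is
what makes the duplicates mechanism lossless: a duplicate position
reuses the stored weight vector verbatim, so topologically equal trees
with different lengths must be distinct unique trees.  Set operations
use the same rule (a topology-only comparison is available behind an
off-by-default flag).  The reference implementation of identity is the
canonical Newick key: children sorted at every node by smallest
descendant taxon, lengths printed at `k` digits.  Deduplication itself
is keyed on frozen sets of `(clade, quantized length)` pairs, which is
the same equivalence relation computed without string building; the test
suite asserts the two agree on randomized collections.

## Hashing

The two universal hashes are modular dot products of the clade bitstring
with seeded random vectors.  Only the worked 6-taxon example fixes
parameters (`m1 = 37`, `m2 = 3701`); defaults elsewhere are a package
choice: `m1` = smallest prime ≥ `max(37, 4·n·⌈√t⌉)` (buckets stay short
as collections grow), `m2` = smallest prime ≥ 10^8 (BID collisions rare),
`R`/`S` drawn from a seeded PRNG with default seed 1.  Record identity
is decided by full-bitstring comparison inside a bucket, never by the
BID, so these choices — and the hash seed itself — cannot change output:
TRZ lines are emitted in a canonical sort order (decreasing set-bit
count, ties by decreasing bitstring text), which the tests pin down by
checking byte equality across hash seeds and input line permutations.
Entries of the example `R` exceed `m1`; since the dot product is reduced
modulo `m1` anyway, parameter validation rejects only negative entries.

## TRZ dialect v1

The component encodings (K/L run lengths, A–J first digits for id
deltas, `+`/`-` for Γ vs Γ̄, +33 byte offset for mantissa digit pairs)
follow the published scheme; the byte-level layout around them is fixed
by this package and documented in `trz_codec.py`:

* run counts for repeated id deltas attach as `M<count>` — `M` is the
  next free letter after the K/L and A–J reservations, and a bare digit
  suffix would be ambiguous against multi-digit delta values;
* `|Γ| = |Γ̄|` ties store the members (`+`), making output deterministic;
* the first id-list element is stored verbatim (a delta from nothing);
* weights always accompany the members, in increasing id order, even on
  `-` lines, since only member trees have them;
* weight payloads are length-delimited (exactly `|Γ|·k/2` bytes, values
  33–132) and never scanned for sentinels — byte 33 is `!`, which also
  opens the integral-exception field, and byte values are otherwise
  arbitrary printable/extended characters;
* a fourth header line `U <u> W <0|1> K <k>` makes files self-describing
  (unique-tree count, weighted flag, mantissa digits);
* duplicate lines `D <uid> <sign><payload>` encode all original
  positions of a repeated unique tree with the same id-list codec over
  the universe `0…t-1`; positions not claimed by any `D` line are
  assigned, in increasing order, to the unique ids without `D` lines in
  increasing id order, which is valid because unique ids are ordered by
  first appearance.

Empty documents (`t = u = B = 0`) are representable; they arise from set
differences and round-trip like any other document.

## Decompression and consensus

Decoding distributes each stored line to the rows of its member trees
(matrices `M` of clades and `N` of aligned lengths).  Because lines are
stored largest-clade-first, each row is already in the order the star
refinement needs: every multi-taxon clade bundles the current children
it fully contains under a new internal node (an overlap that is neither
containment nor disjointness is reported as incompatibility), and
single-taxon clades attach leaf lengths.  A precondition check guards
the ordering rather than re-sorting.

Consensus counts occurrences over all `t` original trees, expanding
duplicates through the position map.  `strict` keeps count = t;
`majority` keeps count > t/2 — the strict inequality is the package's
reading of "majority rule", and it guarantees the kept clades are
pairwise compatible so the refinement cannot fail.  Consensus trees are
emitted without branch lengths; the published procedure does not define
consensus weights, and inventing an averaging rule here would suggest a
precision the data does not have (a mean-length annotation could be
added as an explicit extra).

## Set operations

Union, intersection and difference act on sets of unique trees.  Tree
signatures (frozen sets of `(clade, length)` pairs) are read directly
out of the two documents — no tree structure is rebuilt — and the result
document is assembled from the surviving trees' clade rows, ordered by
first appearance scanning the first operand then the second.  Results
contain unique trees only (`t = u`, no duplicates section).  Operands
must agree on taxa, weighted flag and mantissa precision.  Because
identity is weight-inclusive, no merging rule for conflicting lengths is
ever needed.

## Synthetic collections

The generator emulates the output of a phylogenetic search: heavy clade
sharing and repeated topologies.  Tree 0 is a random rooted binary tree
(sequential random leaf attachment, taxa `T000…`); each later tree is an
exact repeat of a random earlier tree with probability `dup_rate`
(default 0.1), otherwise a copy perturbed by a Poisson(`perturbation_rate`,
default 0.2) number of rooted subtree-regraft moves.  Regrafts rather
than fresh regeneration keep most bipartitions shared — the regime in
which semantic compression wins and the one real samplers produce.
Weighted mode draws 6-digit lengths uniformly in (0, 1), exceeding 1
with probability `integral_rate` to exercise the integral-exception
path.  Everything derives from one seed and is byte-reproducible.

What the generator does *not* emulate: posterior clade frequencies of a
real MCMC run, branch-length correlations along the tree, or taxon
counts in the hundreds with collections of 10^4–10^5 trees.  Passing
round-trip and robustness tests on these fixtures therefore demonstrates
correctness of the algorithms and format, not the compression ratios
reported for large biological datasets; the size property asserted in
tests (TRZ smaller than Newick) is checked in the ≥ 90 %-shared-clade
regime at moderate scale (100 trees, 25 taxa — sizes chosen to keep the
default suite fast while still covering every codec branch).

## Numerical and degenerate cases

* Bitstring sort and text order coincide by construction (taxon `i` maps
  to bit `n-1-i` of the integer), so tie-breaking is integer comparison.
* The all-taxa clade (root) is never stored; single-taxon clades always
  are, so `B ≥ n` whenever `t ≥ 1` and leaf lengths survive round trips.
* Duplicate clades within one tree cannot occur (children of one node
  have disjoint leaf sets); the rebuilder rejects them via the unary-node
  check if a corrupted document supplies one.
* A collection of one tree, all-identical collections, and all-distinct
  collections are all exercised in tests; `u = t` collections simply have
  no `D` section.

## Known limitations

* NEXUS/PhyloXML, quoted labels, internal node labels/support values and
  translation tables are out of scope; taxon names may not contain
  whitespace or Newick punctuation.
* Unrooted semantics are not implemented; callers wanting unrooted
  comparison must root consistently first.
* The TRZ dialect is this package's own; files from other TreeZip
  implementations are not readable.
* Streaming/partial reads are not supported; documents are held in
  memory.
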
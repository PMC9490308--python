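# Methods

## Haplotype identity

A haplotype is an equivalence class of accessions whose sequences at one
marker are indistinguishable. Two regimes are used:

* **Aligned input** (all sequences at the marker share one gapped length):
  alignment columns containing a gap in *any* sequence are excluded, and the
  remaining columns are compared character-for-character. This is the
  behaviour of standard haplotype software operating on alignments, and it is
  the only rule consistent with a panel in which accessions of *different*
  ungapped lengths (differing by indels only) are recorded as the same
  haplotype while their per-accession lengths are reported separately.
* **Unaligned input** (unequal lengths): exact equality of the ungapped,
  uppercased strings; sequences of different ungapped length are always
  distinct.

Ambiguity codes (R, Y, N, …) compare as literal characters in both regimes —
they are rare in finished Sanger consensus sequences, and treating them as
wildcards would make haplotype identity non-transitive. Labels are
`H<k>^<letter>` with `k` the marker's position in the composite code and
letters assigned by first appearance in the panel's accession order (A…Z,
then AA, AB, …); permuting the input order permutes letters but never the
partition.

## Composite codes and discrimination statistics

The composite barcode of an accession is (total ungapped length summed over
markers, ordered tuple of haplotype labels); its partition of the panel is
the common refinement of the marker partitions, so the combined resolved
count is never below any single marker's.

**Terminal taxa.** Accessions are grouped by (genus, species, variety):
named varieties/subspecies are distinct identification targets, while
cultivar names do not split taxa — barcoding is not expected to separate
conspecific cultivars, and the package reports them as an unresolved group
instead. On the packaged 14-accession panel this yields 11 terminal taxa
(10 single accessions plus one four-cultivar species).

**Correct assignment rate (CAR).** CAR = 100 × (distinct haplotype classes
or composite codes observed across the evaluation set) / (number of taxa),
reported to one decimal, round-half-up. The alternative definition —
fraction of taxa carrying a globally unique haplotype — was considered and
rejected: on the packaged panel it yields 75% where the classes/taxa ratio
yields 87.5% (one class shared by two of eight species removes one *class*,
not two taxa), and only the chosen definition is consistent with the panel's
documented per-marker success rates. The same reasoning fixes "accessions
resolved" as the distinct-class count (11 for ITS on the full panel, not the
10 accessions with unique haplotypes).

The discrimination report evaluates three depths: the full panel with
terminal taxa as units (species level), each genus separately with its
varieties/species as units, and each multi-accession species with individual
accessions as units (cultivar level).

## Distances

All models use pairwise deletion: for each pair, sites where either sequence
has a gap or a non-ACGT character are excluded. Transitions are A↔G and C↔T;
everything else is a transversion. K2P:
`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`; with gamma-distributed rate variation of
shape `a`: `d = a/2 [(1−2P−Q)^(−1/a) + ½ (1−2Q)^(−1/a) − 3/2]` (the shape-∞
limit recovers plain K2P; with Q = 2P both reduce to Jukes–Cantor, and both
identities are tested). Saturation (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) flags the
pair as undefined (NaN) rather than clamping to a large value — silent
clamping distorts NJ — and tree construction refuses matrices containing
undefined pairs.

The `num_diff` model returns the raw count of differing comparable sites.
A gamma correction of a raw count is not mathematically meaningful (the
correction acts on per-site divergence), so `num_diff_gamma` computes the
same raw count and records no shape parameter; `k2p_gamma` (default shape 1)
is the model to use when gamma rate variation is wanted.

## Neighbor-Joining and bootstrap

Saitou–Nei agglomeration with the Studier–Keppler criterion
`Q(i,j) = (n−2) d(i,j) − r(i) − r(j)`. Ties (differences below 1e−15) break
to the lowest index pair, making the topology deterministic. Branch lengths
use the standard three-point formulas; negative estimates are clamped to
zero with the count and total deficit recorded on the tree and surfaced in
the run manifest. Trees are unrooted (internal nodes of degree 3); rooting
is a display concern only.

Bootstrap resampling draws alignment columns of the (concatenated) matrix
with replacement — not stratified per marker, the simplest form of the
standard procedure — rebuilds the NJ tree per replicate, and reports for
each internal edge of the original tree the percentage of replicates whose
tree contains the same leaf bipartition (supports annotate the data tree,
not a consensus). Replicates whose resampled matrix has undefined pairs
contribute no bipartitions but remain in the denominator. A single integer
seed drives one `numpy` Generator per bootstrap run; identical seed and
input give identical supports and output bytes.

Monophyly of a leaf set is bipartition membership: the set (or its
complement) must be induced by some edge of the unrooted tree; singletons,
(n−1)-sets and the full set are trivially monophyletic.

## Synthetic data

**Fixture generator.** The packaged table (`data/fixture_tables.yaml`)
transcribes the documented panel: 14 accessions in 7 genera, four markers,
per-accession ungapped lengths, and the per-marker haplotype letters. For
each marker a random base sequence (seeded `numpy` Generator) of the
marker's maximum length is drawn; each haplotype class receives
`min_class_divergence` (default 1) deterministic substitutions in its own
window placed inside the region every sequence covers; each accession takes
its class's sequence truncated to its tabulated length and padded with
terminal gaps to the common alignment length. By construction, for every
seed: lengths match the table cell-for-cell, the collapse partition equals
the tabulated letters, distinct classes differ by at least the minimum
divergence, and the panel doubles as per-marker alignments (multiple
sequence alignment is out of scope). The audit of these postconditions is
itself a test.

What the fixture does *not* emulate: real base composition, the actual
substitution spectrum between taxa, indel placement (all length variation is
terminal), and real inter-class divergence magnitudes (classes differ by few
substitutions, so fixture trees have short, arbitrary branch lengths). Green
fixture tests therefore establish that the *combinatorial* pipeline —
collapsing, codes, counts, rates — reproduces the documented numbers, not
that any particular published tree shape or branch-length sum is recovered;
the published trees derive from unpublished sequences and are explicitly not
reproduction targets.

**Divergence simulator.** A genus → species → accession hierarchy; per
level, each lineage copies its parent sequence and substitutes each site
independently with the level's rate, choosing a transition with probability
κ/(κ+1) (κ = ts/tv ratio, default 2.0) and otherwise a uniform
transversion. Defaults mirror the study's design: 7 genera × 2 species × 2
accessions, marker lengths ITS 700 / matK 400 / rbcL 572 / trnL-F 460 bp,
rates genus 0.05, species 0.01, accession 0.0 per site (the study found no
within-species variation, so conspecific accessions are labelled cultivars).
No indels, recombination, or coalescent variance. The true genealogy is
returned for recovery experiments; with the default rates the 4-marker NJ
tree keeps every genus monophyletic and the combined code separates all
terminal taxa.

## Numerical conventions

* Percentages: one decimal, round-half-up (`decimal.Decimal`).
* Newick output: 8 significant digits on branch lengths, supports as integer
  internal-node labels; write→read→write is byte-stable.
* Machine rendering of codes uses `|` separators and `.` instead of
  superscripts (`L2127|H1.A|…`) for bit-stable output.
* Exit codes of the CLI: 0 ok, 2 usage, 3 data validation, 4 computation.

## Known limitations

* Haplotype collapsing on aligned input excludes gap columns globally
  (complete deletion), so a substitution inside another accession's indel
  region is invisible to identity; the fixture places class differences
  outside such regions.
* The CAR can exceed 100% if an evaluation set harbours more haplotypes than
  taxa (within-taxon variation); the package reports the raw ratio.
* The NJ implementation is O(n³) pure NumPy/Python — ample for barcoding
  panels (tens of accessions), not for thousands of taxa.
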
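# Methods

## Coordinate and interval conventions

All intervals are 0-based half-open (BED convention); GFF3 input is converted
at the boundary, so `end - start` is always a length in bases. Interval
arithmetic is strand-agnostic: a repeat mask is a set of genomic bases.
Touching intervals merge (a base-level mask has no meaningful zero-width gap),
and merge/intersect/coverage are computed by sort-and-sweep over the merged
representations, which makes every count an exact integer. Records extending
past the bound chromosome length are rejected rather than clipped so that a
fixture/index mismatch surfaces at load time. Window grids tile each
chromosome from 0 and keep the trailing partial window, so window lengths
always sum to the genome length; callers that want equal-length windows can
filter on length.

## Concordance model

Window presence uses the any-overlap rule (≥ 1 masked base ⇒ 1), with a
`min_bases` option for stricter definitions. Clustering is complete-linkage
agglomeration on Euclidean distances between the binary method columns,
computed from the full method × method distance matrix (methods are few, the
window dimension is large). Methods are canonicalized to lexicographic order
before linkage, which makes the dendrogram deterministic and invariant under
permutation of the input sets; complete linkage guarantees non-decreasing
merge heights. Pattern ranking excludes the all-zero pattern — those windows
carry no information about tool behaviour and would otherwise dominate every
ranking — and breaks count ties lexicographically.

Pairwise agreement is base-level by default, normalized by the *compared*
method's mask: a tool whose calls are a subset of the reference scores 1.0
even if the reference masks far more. This asymmetric definition captures
"tool A's calls are incorporated by tool B" and is the documented default; a
window-level mode is available behind a flag.

## Repeat–gene overlap rules

Containment of a single-exon transcript is tested against the merged per-class
mask (default), so an element fragmented by the annotator still contains the
exon; a `raw_elements` mode reproduces single-element (BEDTools `-f 1`-style)
behaviour for comparison. Fractional coverage is inclusive at the threshold
("at least 50 %"), computed as an exact integer ratio; the 0.5 default is
exactly representable, so the boundary case is decided without floating-point
ambiguity. Superfamily attribution goes to the raw element with the largest
single-element overlap; ties break lexicographically with all tied
superfamilies retained in a secondary field. The ≥ 20-transcript tally counts
each transcript once per superfamily and skips classes that carry no
superfamily by construction (simple repeats, low-complexity, unknowns).

## Phylostratigraphy

Age class = the largest species index with a qualifying hit (strict
`e-value < threshold`, default 1e-5), 0 when there is none; non-monotone hit
patterns are allowed and only the maximum matters. Hit tables whose values are
all in {0, 1} are read as indicators, anything else as e-values; NaN entries
are rejected — "no hit" in an e-value table must be encoded as a value at or
above the threshold. Empty age classes report NaN fractions, never 0, to keep
"no genes" distinguishable from "no overlap".

## Classifier consensus

Votes are taken at the two-class level (DNA transposon vs retrotransposon),
where the order-level labels map deterministically (DNA/RC → DNA transposon;
LINE/LTR/SINE/Penelope → retrotransposon; everything else Other). With three
voters a three-way split requires an Other/Unknown vote, and such elements are
reported AMBIGUOUS. When an external truth channel is supplied, error rates
are computed over all elements; against the majority consensus, AMBIGUOUS
elements are excluded from the denominator (a documented choice — the
reference is undefined there).

## Synteny

Only families that are single-copy on both scaffolds can anchor an alignment;
multi-copy families (transposons among them) may only be insertion targets.
Because anchors are single-copy, the LCS over anchor tokens reduces to a
longest-increasing-subsequence problem solved in O(n log n); both orientations
of the partner scaffold are tried and the longer chain kept (tie → forward).
Focal scaffolds are paired with whichever outgroup scaffold yields the longest
anchor chain. For each maximal run of target-family genes, the nearest
flanking chain anchors are located independently per outgroup; a call requires
flanking anchors on both sides in both outgroups, at most `max_gap`
(default 2) intervening non-target, non-anchor focal genes, and no
target-family gene between the matched anchors in either outgroup. The
per-outgroup anchor rule (rather than demanding one shared anchor pair) is the
package's operationalization: the two chains drop different genes under local
rearrangement, and requiring a shared pair would miss real insertions whose
flanks are anchored differently against each outgroup. `max_gap = 2` absorbs
small local rearrangements without admitting unrelated gene gain.

## Synthetic-data generator

The generator emulates the study conditions at desk scale and returns a
ground-truth registry alongside every fixture; tests compare analysis output
to the registry, never to quantities re-derived from the fixtures.

* **Genome and repeats.** Three chromosomes totalling 1 Mb. Per-class planted
  densities sum to ~20 % of the genome — inside the 12–24 % band that brackets
  repeat content in nematode genomes — with gamma-distributed element lengths
  (means 80–1500 bp by class) and superfamily mixes concentrated on the
  superfamilies most often seen with transcriptional support (CR1, RTE,
  Sola-3, TcMar-Tc1, Gypsy, Pao, Helitron, Zisupton). Retroelement classes
  (LINE, LTR, Penelope) carry an arm bias (position weight 1 + 2·2|x − 0.5|)
  emulating arm enrichment; DNA transposons are uniform. True elements never
  overlap one another — across classes too — so per-class placed bp is an
  exact density oracle; real genomes contain nested insertions, which this
  deliberately omits (nesting is exercised separately through tool masks and
  hand-built unit fixtures).
* **Tools.** Six emulated annotators. Two pairs (rm2/red, dustmasker/sdust)
  each derive from a shared latent subsample of the true mask and then drop
  latent elements independently at 5 % flip noise, planting the correlated
  pair structure; two independent tools have distinctly lower sensitivities
  (0.70, 0.40) so they cannot mimic a pair. All tools jitter endpoints
  (normal, sd 4–15 bp) and add unlabelled false calls (0.5–2 % of the
  genome).
* **Gene models.** The single-exon channel plants transcripts fully inside
  elements of configured superfamilies (six at or above the 20-transcript
  cutoff, two below), 1-bp-shortfall transcripts (exon exceeds its element by
  exactly one base), and repeat-free transcripts sized so contained
  transcripts are ~14 % of the channel. The annotated channel plants two-exon
  genes with one exon at coverage exactly 0.5, genes one base below 0.5,
  repeat-free genes, and multi-isoform genes with overlapping exons for the
  merge path. Planted exons are re-checked against every class mask at
  generation time so no unplanned record can appear.
* **Homology ladder.** 5000 genes over a 9-species ladder; age-class
  proportions put ~30 % in class 0 (orphan-rich genomes) and ~20 % in the
  oldest class. Hit rows are monotone up to the defining species (nearer
  species hit with probability 0.9) with optional sporadic distant hits; the
  registry records the realized class (max hit index), so it stays correct
  when sporadic hits promote a gene. Per-class repeat-overlap fractions are
  planted exactly as round(f · class size); the simple-repeat series rises
  from 6.0 % to 18.6 % with a dip at class 5, and TE classes sit at 3–5 % per
  class so the summed TE contribution stays in the 10–20 % band.
* **Classifier labels.** Truth is a 50/50 DNA/retrotransposon mix with
  order-level detail; methods flip the class at rates (0.05, 0.15, 0.25),
  reporting a random order of the opposite class when flipped. Error rates
  against truth therefore estimate the flip rates directly.
* **Gene orders.** Two scaffolds of 250 families per species (500 genes per
  species across three species); 20 insertions of a multi-copy target family
  planted in the focal order; one pass of adjacent transpositions at rate
  0.05 per position models local rearrangement; 2 % duplicated families and
  2 % per-species UNASSIGNED tokens exercise the anchor filter; the second
  outgroup's scaffolds are reversed to exercise orientation handling.

Reproducibility: one global seed feeds named substreams (PCG64 spawned with
CRC32-keyed spawn keys), so identical configs give byte-identical fixture
files and adding a generator never perturbs existing ones.

What passing these tests shows — and does not. Recovery of planted structure
demonstrates that the algebra, the clustering, the overlap rules and the
detectors are implemented correctly under the stated noise models. It does not
show that the defaults match any particular real genome: the generator places
intervals and labels only (no nucleotide sequence), omits nested insertions
among true elements, uses a single round of adjacent transpositions as its
rearrangement model, and draws tool errors independently per element, whereas
real annotation errors are correlated along the sequence.

## Problem sizes and numerical choices

The default study (1-Mb genome, 1000 one-kb windows, 5000 genes, 2000
labelled elements, 3 × 520-gene orders) is the package's chosen desk scale:
large enough that sampling noise is small against the planted effects, small
enough that the full test suite and the acceptance script each run in well
under a minute of compute per stage. Multi-seed properties use 100 seeds
(clustering, classifier ranking) or 50 seeds (insertion detection). All
interval counts are exact integers; the only floating-point quantities are
fractions of integer counts and Euclidean distances. Dendrogram ties are
resolved by canonical method order; pattern and tally ties lexicographically;
LIS tie-breaking follows patience sorting (earliest achievable tail), with
orientation ties resolved toward forward.

## Known limitations

Agreement ranges and window counts on the synthetic study are not comparable
to values measured on a real ~170-Mb assembly with the actual external tools;
only the relative structure (pair recovery, ordering of agreement values) is
designed to transfer. The containment default (merged per-class mask) can
report containment where every raw element covers only part of an exon;
`raw_elements` mode exists precisely to quantify that difference. The synteny
detector assumes the outgroup species are correctly chosen as the two closest
relatives; it does not itself verify outgroup topology.
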
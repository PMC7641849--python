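# Methods

## Gene neighborhoods

The unit of analysis is the *neighborhood*: the window of up to `W` genes
on each side (default `W = 10`) of a gene carrying the anchor domain, on a
single contig. Windows are counted in genes, not base pairs; strand is
recorded but ignored for membership, since operonic association is a
proximity statement and annotation of gene orientation is uneven across
genomes. Windows are truncated at contig ends rather than spliced across
contigs — physical continuity of the neighborhood is the premise of the
analysis. Coordinates are 1-based inclusive (GenBank convention); a 0-based
half-open source can be declared at read time.

Duplicate neighborhoods — identical concatenated domain compositions in
coordinate order — are collapsed to the first occurrence. Deduplication is
global across the input by default (a census counts unique compositions,
not unique compositions per genus); per-genus scoping is available as an
option.

## The 1/(n+1) association statistic

For a pair of domains co-occurring in a neighborhood, the association is
`1/(n+1)`, with `n` the number of domain occurrences encoded by *distinct
genes strictly between* the pair members in coordinate order. Domains, not
genes, are counted: a fused gene between the pair contributes every one of
its domains; an unannotated gene contributes nothing. A fusion carrying
both pair members scores `n = 0`, i.e. association 1.

Three resolutions the statistic itself does not fix:

- **Multiple occurrences.** When either domain occurs more than once, the
  closest occurrence pair (maximum score) is used — the tightest operonic
  linkage is the signal of interest. A self-pair (domain with itself) is
  scored only when the domain occurs on at least two distinct genes.
- **Absence is not zero.** A genus mean averages the score over only those
  neighborhoods of the genus in which the pair co-occurs; neighborhoods
  without the pair are not counted as zeros. The alternative (pooled,
  count-weighted averaging) is available as `genus_weighting="count"`.
- **Hierarchy.** The overall association is the unweighted mean of the
  genus means over genera with at least one co-occurring neighborhood. The
  two-level structure itself is the weighting: it prevents a single
  heavily sequenced genus from dominating.

Scores are kept as exact rationals (`fractions.Fraction`) through both
averaging levels and converted to floats only at export, which removes
rounding ambiguity when comparing against enumeration oracles.

## Contextual network

The network retains the `K` highest overall means over *all* pairs
(default `K = 400`), not only anchor-incident ones — partner–partner edges
are part of the context signal. Ties at the cutoff break by lexicographic
pair order, fixing determinism. Pruning is for legibility, not inference:
degree-1 nodes whose only edge reaches the anchor are dropped, then
non-anchor components below a minimum size (default 3; no principled value
exists, it is configurable). The edge budget is applied before pruning.
Exports (GraphML, TSV) carry weights to 12 significant digits and
round-trip losslessly.

## Midpoint rooting and divergence fractions

Trees are carried as `dendropy.Tree` objects; Newick I/O preserves branch
lengths to better than 1e-9. Midpoint rooting is implemented directly (the
longest tip-to-tip path is found exhaustively, and the root placed halfway
along it) with fixed tie rules: among equally long paths the
lexicographically smallest tip-label pair wins, and a midpoint falling
exactly on a node (possible with zero-length branches) roots at that node.
The placement provably minimizes the maximum root-to-tip distance; the
test suite checks this against brute-force root placement on every edge
and against an independent library's midpoint rooting.

Tree height is the median of root-to-tip distances, with quartiles by
linear interpolation between order statistics (the inclusive method) —
several quartile conventions exist, so one is declared and fixed. A
group's subtree is the minimal path-preserving subtree over its tips,
rooted at their MRCA within the midpoint-rooted full tree; re-rooting each
subtree at its own midpoint is available as an option and typically shifts
fractions by at most a point or two. The divergence fraction is
`100 · median_subtree / median_full`, rounded half-up to an integer
percent.

## Schematic-tree pipeline

The pipeline condenses a large family into a two-level tree. All external
heavy tools whose role it mirrors (fast greedy clusterers, multiple
aligners, profile–profile search, ML tree builders) are replaced by
declared simplified algorithms so the pipeline is self-contained and
deterministic; each step sits behind its own function and can be swapped.

- **Pairwise identity** is global alignment (match 1, mismatch 0, linear
  gap −1; Needleman–Wunsch via Biopython) with identity = identical
  columns / alignment length.
- **Greedy clustering** processes sequences longest-first (ties by id) and
  assigns each to the first cluster whose representative matches at the
  threshold (default 0.5), else founds a new cluster. Representative
  selection at 0.85 identity (`select_representatives`) provides the
  de-redundancy step that precedes a census.
- **Cluster alignment** is center-star against the representative: each
  member is aligned pairwise and merged column-wise ("once a gap, always a
  gap"). The profile is the per-column residue frequency over non-gap
  characters (21-letter alphabet, X included).
- **Profile similarity** is the best ungapped-offset column-dot-product,
  background-corrected: each overlap column contributes
  `p_a · p_b − 1/20`, the uniform-background expectation, so chance
  similarity between unrelated profiles scores near zero — the behavior of
  log-odds profile scores, which the merge-ratio threshold presumes.
  Offsets are restricted to overlaps of at least half the shorter profile.
  The self-score is the zero-offset score of a profile with itself; the
  merge ratio divides the pair score by the *smaller* self-score, the
  conservative (larger-ratio) choice.
- **Merging** runs for a fixed number of rounds (default 5): all pairs
  with ratio > 0.1 are merged transitively (union-find), merged clusters
  are realigned (only merged ones — untouched clusters keep their
  alignments), and iteration stops early once no pair qualifies. The
  cluster count is non-increasing.
- **Backbone** is UPGMA (SciPy average linkage) on
  `d = 1 − s/max(s)` over the similarity matrix, a monotone, bounded,
  parameter-free conversion; node heights are half the merge
  dissimilarity, so the dendrogram is ultrametric. Labels are pre-sorted
  lexicographically so ties resolve deterministically.
- **Member trees** are neighbor joining (scikit-bio) on p-distances from
  the cluster alignment (columns where both rows are non-gap; distance 1
  if none), negative NJ branch lengths clamped to zero, then
  midpoint-rooted. Two-member clusters form a cherry with p/2 per side;
  singletons a one-tip tree.
- **Grafting** replaces each backbone tip with its cluster's member tree,
  preserving backbone branch lengths. The composite tip set is exactly the
  input sequence set, and identical inputs yield byte-identical Newick.

## Synthetic data

- **Genomes.** One contig per genome; each gene carries one background
  domain i.i.d. with probability 0.9 from a 25-domain pool; one anchor
  gene per genome; operon templates (default: anchor + 3 partners laid
  down adjacently, insertion probability 0.9 — the arrangement of the
  conserved α-proteobacterial EVE operon) are placed on the genes
  following the anchor, with optional 0–2 background genes of jitter
  between members. Defaults are 10 genera × 10 genomes × 60 genes. The
  high background attachment rate matters: with most genes annotated,
  `n` tracks gene distance and random pairs average well below the
  planted adjacent pairs' 1.0. Not emulated: multi-contig genomes,
  strand structure of operons, horizontal transfer, genus-specific domain
  repertoires — so recovery tests show the statistic separates planted
  contiguity from positional noise, not that it is robust to phylogenetic
  confounding.
- **Two-rate trees.** Two clades of 20 tips; clade *k*'s ancestor sits at
  depth `(1 − r_k)·H` and its tips at depth `H` (default `H = 2.82`, the
  scale of a deep domain tree), so clade medians from the MRCA are
  `r_k·H` and divergence fractions are `100·r_k` exactly at zero noise.
  The stem lengths are therefore derived from the scalers rather than
  free parameters. Multiplicative Gaussian noise (default 5 %) perturbs
  tip depths; internal nodes are placed at uniform random fractions of
  the available depth. No substitution process is simulated — the
  generator controls path lengths directly.
- **Sequence families.** Family roots are a common random ancestor
  mutated at the between-family rate (1.0 = unrelated roots, cross-family
  identity at the ≈ 5 % background of a 20-letter alphabet); members are
  the root mutated i.i.d. per site at the within-family rate (default
  0.08, giving ≈ 0.85 within-family identity), substitutions always
  changing the residue so rates equal expected p-distances. Indels are
  off by default. This exercises clustering; it is not a claim of
  realistic sequence evolution (no rate heterogeneity, no alignment
  ambiguity beyond optional indels).

## Problem sizes and runtime

The validation suite runs at desk scale by choice: 20-replicate recovery
experiments use 100 genomes (6,000 genes) per replicate for associations,
40-tip trees for divergence, and 24–200 sequences of length 120–150 for
the cluster pipeline; midpoint optimality is checked exhaustively on trees
of up to 8 tips at 100 candidate positions per edge. The whole suite
completes in well under a minute on one core.

## Known limitations

- The greedy clusterer is order-dependent by construction (longest-first
  is fixed for determinism); it approximates, not reproduces, MMseqs2-style
  clustering.
- Center-star alignment is O(members × length²) and does not refine; for
  very divergent clusters its profiles are noisier than a full MSA's.
- The association statistic carries no significance model; ranking, not
  inference, is its contract.
- Neighborhood extraction counts every supplied gene row; if a source
  annotates pseudogenes or ncRNA genes inconsistently, window contents
  shift accordingly.
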
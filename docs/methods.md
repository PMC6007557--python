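# Methods

## Origin classification

The unit of evidence is the HSP (high-scoring pair) of a protein–protein
homology search of the focal genome's proteins against a broad reference
database. The pipeline consumes such a search's tabular output, extended
with the subject taxon and percent amino-acid similarity, because
classification needs a taxon per hit without a live taxonomy service.

Filtering removes self-hits (subject taxon equal to the focal species, or
subject id equal to the query id) and low-quality HSPs: those covering
< 90% of the query protein or with similarity < 40%. Because the rule is
phrased as removal of strictly-sub-threshold HSPs, exact-threshold hits
are retained (boundary inclusive, `>=`). Filters apply per HSP; a subject
qualifies if any of its HSPs passes and is represented by its best-scoring
passing HSP. Subjects are ranked by descending bit score with ties broken
by ascending subject id, making runs reproducible under any input row
order, and up to five top subjects are kept per query.

The four-way verdict depends only on that top-5 set: empty →
`species_specific`; all focal-clade → `native`; no focal-clade →
`hgt_high`; mixture → `hgt_low`. Whether the similarity column means
alignment "positives" or strict identities is deliberately left to the
input: the pipeline treats it as an opaque percentage, and the synthetic
generator emulates positives.

A gene entirely absent from the raw hit table is an input-completeness
error by default rather than an orphan; the `absent_means_no_hits` flag
restores the permissive reading. This guards against silently inflating
orphan counts from truncated hit tables.

### Donor assignment

No published procedure exists for assigning a single donor clade per gene,
so the package uses the simplest deterministic rule consistent with a
single-donor-per-gene accounting: plurality of the evidence hits' clades,
ties broken by larger summed bit score, then lexicographic clade label.
Low-confidence candidates get the same vote over their non-focal hits
only, flagged `tentative`; island detection ignores them by default.

### Gene-tree candidate selection

For gene-tree analysis the filter is relaxed to coverage ≥ 80% and
similarity ≥ 30% to admit more distant homologs, the hit list is extended
to the top 100 subjects, and a high-confidence acquired gene qualifies
when at least five hits come from focal-clade species other than the focal
genome itself.

## Island detection

An acquired island is a maximal run of same-donor `hgt_high` genes with at
least `min_genes = 5` members. Contiguity is not defined in the
literature this pipeline operationalises, so it is a parameter: up to
`max_gap = 2` genes of any other class or donor may interrupt a run
between two members. The tolerance accommodates unclassified orphans
inside transferred regions while keeping islands near-contiguous. Runs are
chained on the circle, so islands may cross the replication origin; each
gene belongs to at most one island and island gene sets are pairwise
disjoint (runs of different donors may interleave only across bridged
gaps). When every member of a donor chains all the way around the circle,
the canonical run starts after the widest inter-member gap.

The optional synteny screen is likewise an operationalisation: the island
members' best-hit subject ids, in chromosome order, must share an ordered
common subsequence of length ≥ `min_genes` with a supplied donor gene
order, read forward or in reverse (inversions allowed). It is off unless a
donor order file is given; islands are then annotated rather than
filtered.

## Summary statistics

Printed-style percentages are integers rounded half-up (computed on exact
rationals to avoid binary-float edge cases). Per-class chromosome-length
fractions divide the summed nucleotide spans of the class's genes by the
chromosome length; intergenic and RNA-gene DNA belongs to no class, which
is why the four length percentages sum below 100. Origin-wrapping genes
(end < start on the circular chromosome) contribute their modular span.

GC content and GC skew are computed in sliding windows (defaults 10 kb
window, 1 kb step — small enough to resolve rRNA-cluster-scale GC peaks)
that wrap the origin on circular replicons. N bases are excluded from the
GC denominator; an all-N window is a missing point, and a G+C-free window
has skew 0 by convention, flagged `degenerate`. Ambiguity codes other
than N are rejected at FASTA load so the denominator rule stays simple.

Cross-species class averages are unweighted means of per-species
percentages (each row's own four-class total as denominator), matching the
"on average across species" reading; rows marked `reference_only` in the
packaged count table (the divergent outgroup species for which best-hit
classification is not applicable) are excluded. The PFGE discrepancy is
`100 * (pfge - assembled) / pfge`, rounded half-up.

## Synthetic data generator

The generator emulates the statistical object the classifier actually
sees — taxonomic composition of ranked, filtered hit lists — not sequence
evolution. Defaults are the flagship study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 1,346 | protein-coding genes |
| `chrom_len_bp` | 1,560,000 | circular chromosome length |
| `class_fractions` | 641/472/142/91 over 1,346 | native, orphan, hgt_low, hgt_high |
| `donor_clades` | 0.38 / 0.13 / 0.17 / 0.32 | Mycoides-Entomoplasmataceae, Citri-Chrysopicola-Mirum, other Mollicutes, non-Mollicutes |
| `island_sizes` | (7,7,7,6,6,6,6) | seven planted islands, 45 genes |
| `n_tree_candidates` | 9 | acquired genes with ≥ 5 relaxed focal homologs |
| `cog_probs_acquired` | G = 0.51, rest spread | COG letters of acquired genes |
| `hits_per_gene_range` | (6, 12) | raw hit rows per gene |
| `similarity_noise_sd` | 0 | Gaussian noise on similarities (%) |
| `borderline_fraction` | 0 | hits placed within ±ε of the strict threshold |
| `base_gc` | 0.26 | AT-rich chromosome background |

Class counts, donor clades, and acquired-gene COG letters are apportioned
by largest-remainder quota over the configured fractions rather than
multinomial draws, so fixture composition equals the configured conditions
exactly; residual randomness (placement, hit counts, scores, lengths)
flows from the mandatory seed. Mean protein lengths differ by class
(native 365 aa, orphan 318, hgt_low 328, hgt_high 342, ±30% spread) —
orphan genes run shorter, as species-specific ORFs tend to — which makes
the expected length fractions track the count fractions the way real
genomes do. At the defaults this gives ≈ 89% coding density.

Hit construction works backwards from the intended verdict: native genes
get passing focal-clade hits; high-confidence acquired genes get 5–7
passing donor-clade hits ranked above 0–3 passing focal hits (exercising
the top-5 cutoff); low-confidence genes get a shuffled focal/donor mixture
in the top 5; orphans get either nothing or only failing hits. Tree
candidates additionally get ≥ 5 focal hits that pass only the relaxed
filter (similarity 32–38%, coverage 0.82–0.88). Bit scores decrease with
intended rank with jitter bounded so ranks never invert; a self-hit row is
included with probability 0.7 to exercise self-removal.

Borderline hits are placed within ±max(1, 2·sd) of the 40% similarity
threshold (or, deterministically, at the exact coverage boundary) on their
intended side and recorded per gene in the truth table. Similarity noise
is added to every hit, but non-borderline hits are clamped to a ≥ 2-point
margin on their intended side, so *only* recorded borderline hits can flip
across a filter — at zero noise the round trip is lossless for every
feasible configuration, and with noise every misclassified gene provably
carries a borderline hit. Planted acquired features are spaced at least
four genes apart so the default gap rule cannot chain two of them into a
spurious island, keeping island-level truth exact.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: real protein sequences and alignment scores,
database bias and taxon sampling holes, paralogy and domain-level partial
homology, annotation errors in the gene inventory, and donors absent from
the taxonomy. Results on real genomes inherit all the caveats of best-hit
classification against an incomplete database.

Recovery is scored with a 4×4 confusion matrix and per-class accuracies;
a detected island matches a planted one when the Jaccard index of their
member sets is ≥ 0.5, matched greedily one-to-one in decreasing Jaccard
order, giving island precision and recall.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (GFF3 convention); BED
  output is 0-based half-open, with origin-wrapping islands split into two
  BED lines sharing a name.
- The GFF3 reader is a purpose-built subset parser because the dialect
  permits end < start for origin-wrapping genes, which generic GFF3
  libraries reject; FASTA goes through Biopython.
- The generator writes one raw hit table; the strict and relaxed views are
  derived downstream by the filter policies, mirroring how a single search
  output is filtered two ways.
- All output files are written atomically (temp file, then rename); run
  provenance (parameters, input SHA-256 checksums, package version) is
  written beside every CLI output, without timestamps so repeated runs are
  byte-identical.
- Exit codes: 2 missing input, 3 validation failure, 4 internal
  inconsistency (e.g. summary counts disagreeing with classifier counts).

## Known limitations

- Best-hit classification cannot separate ancient transfers, multiple
  gain/loss histories, or database absence; the low-confidence class and
  the orphan class absorb those cases by construction.
- Island calls depend on the `max_gap` operationalisation; there is no
  nucleotide-resolution breakpoint refinement and no alignment-based
  synteny.
- The hit table is trusted as given: no E-values, no alignment
  recomputation.
- Donor fractions are reported per gene; per-island accounting would
  differ when islands are large.
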
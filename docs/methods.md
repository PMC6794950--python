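# Methods

`barcode-eval` evaluates candidate DNA-barcode loci (and their
concatenations) for species discrimination in a taxon-rich sampling design,
and ships a seeded simulator so the whole pipeline can be validated against
known truth. This note records the models, the conventions chosen where the
field's tools disagree, and what the synthetic data do and do not show.

## Data model

A dataset is a set of per-locus aligned FASTA files whose headers carry a
`Genus_species|sample_id` label. All analyses run on the ingroup; outgroup
species or samples are excluded from every statistic but may stay in trees.
Samples present in some loci and absent in others (failed amplification) are
handled per combination: a concatenated barcode keeps only samples that have
every member locus. The alternative — padding with `?` — would silently
shrink the effective overlap of pairwise comparisons and bias distances
downward, so dropped samples are listed instead. Column coordinates in
partition records are 0-based, half-open.

A *singleton* species (one sampled individual) is never part of a
discrimination numerator or denominator but stays in the dataset as a
potential nearest neighbour — singletons can cause failures but cannot
succeed or fail themselves. All rates reported by the package are
per-individual: every individual of a discriminated species counts as one
success out of all individuals of multi-individual species. The two integer
counts are carried alongside every rate.

## Sequence characteristics

Site classification follows the MEGA/DnaSP convention: only unambiguous
A/C/G/T establish variability; gaps, `?` and IUPAC ambiguity codes are
missing data at a site. A column is *variable* with ≥ 2 distinct bases, and
*parsimony-informative* when ≥ 2 distinct bases each occur in ≥ 2 sequences.
An *indel event* (DIP-style) is a maximal run of columns over which the
identical, non-empty set of sequences is gapped; runs differing in their
gapped-sequence set are distinct events, and event lengths are reported in
columns. Published tools do not document their event logic precisely, so
this definition is declared rather than reverse-engineered; it reproduces
the common case (a shared deletion = one event, overlapping independent
deletions = several) and is what the simulator's indel model produces.

## K2P distances

Pairwise distances use the Kimura 2-parameter estimator with *pairwise*
deletion: for each pair, columns where either sequence has a gap, `?` or an
ambiguity code are removed; with transition proportion P and transversion
proportion Q over the remaining n sites,

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)].

Pairwise (not complete) deletion is the MEGA default and matters for
variable-length loci such as trnH-psbA, where complete deletion would
discard most columns. The distance is *undefined* when n = 0 or the log
argument leaves its domain (saturation); undefined values propagate as
flagged NaNs rather than exceptions, so a single saturated outlier cannot
abort a whole-matrix analysis. They are excluded from summaries (with the
exclusion visible in pair counts) and are a hard error only where a method
cannot proceed without them (tree building). Distances are kept at full
precision internally and rounded to 4 decimals only in reports.

## Barcoding gaps and PWG discrimination

The intra/interspecific distance distributions are binned on a shared grid
(default bin width 0.005, chosen for visual granularity; configurable). A
*global* gap exists when max(intra) < min(inter). The *local* criterion is
per species: success iff the smallest distance from any member to any
non-member strictly exceeds the species' largest within-species distance.
Ties fail — the criterion is "larger than", and a shared haplotype between
two species yields a 0 = 0 tie that should not count as discrimination.

## Best Match / Best Close Match

Each eligible query (individuals of multi-individual species) is assigned
the species of its nearest non-self neighbour. Ties within a relative
tolerance of 1e-9 keep the whole tied set: all-conspecific → correct, mixed
→ ambiguous, none-conspecific → incorrect. Best Close Match additionally
demotes queries whose best distance exceeds a threshold to "no match"; the
threshold defaults to the 95th percentile (linear interpolation) of all
intraspecific distances, the TAXONDNA convention. The relative tie
tolerance exists because exact float equality is meaningless after a log
transform; 1e-9 is far below any biologically distinguishable distance and
far above double rounding error.

## NJ trees, bootstrap, monophyly

Neighbor joining is the classical Saitou–Nei agglomeration with the
Q-criterion. Two determinism conventions are imposed: Q-ties are broken by
the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf label), and negative branch lengths are
clamped to zero with the excess moved to the sister edge, preserving the
pairwise path lengths through the joined node. Bootstrap resamples columns
with replacement; each replicate is re-distanced and re-joined, and support
for each internal bipartition of the original tree is the percentage of
replicates containing it. Replicates with undefined distances are skipped;
more than 20% skipped aborts the run. A species is *discriminated* when
some edge isolates exactly its samples (unrooted: either side of the edge)
with support strictly above 50 — "greater than 50%", so exactly 50 fails.
On a tree built without bootstrap, monophyly verdicts are topology-only
(support reported as absent and not gated); discrimination rates always use
bootstrapped trees.

## The simulator

The generator emulates the structure of a genus-scale barcoding study:

- **Species tree** — pure-birth (Yule): with k lineages the next split
  waits Exp(k·λ), plus one final stretch after the last split so tips do
  not sit on a split. E[root depth] = (1/λ) Σ_{k=2..n} 1/k, which the tests
  use as a closed-form oracle. The tree can be rescaled to a target root
  depth and/or given a *divergence floor*: every terminal branch is
  extended equally until the closest species pair is at least a target
  distance apart. The floor (rather than a whole-tree rescale) keeps deep
  paths bounded, which keeps fast loci out of K2P saturation.
- **Individual genealogies** — each species leaf expands into a caterpillar
  of its samples with coalescent depths Exp(mean = intra-depth), truncated
  to the terminal branch. All plastid loci share one genealogy per
  individual; the nuclear locus draws its own, reflecting their different
  inheritance.
- **Chloroplast capture** — with a configured probability per sister pair
  (or forced on one pair), every recipient-species sample is re-attached as
  a zero-height sister of a donor-species sample leaf in the plastid
  genealogy, i.e. it carries an exact copy of a donor haplotype. This is
  the simplest mechanism that reproduces the cyto-nuclear discordance
  signature deterministically: tied zero interspecific distances make both
  species fail the local-gap criterion, and mixed donor/recipient cherries
  make both non-monophyletic, while the nuclear locus is untouched.
- **Sequences** — root drawn uniform over A/C/G/T; along each branch the
  K2P transition matrix with ratio κ (= α/β; default 2) is applied exactly
  via its closed-form P(t), Q(t). Indel events are Poisson-many per locus,
  each borne by one branch and gap-coded in all its descendant samples, so
  alignments stay rectangular without running an aligner.
- **Preset** — the `pulsatilla-like` profile: 19 species in 3 clades, 52
  samples (counts 5,5,5,4×7,1×9 → 9 singletons), four loci with lengths
  1207/835/379/589 and rate multipliers 1 : 1.8 : 1.7 : 9.2
  (rbcL : matK : trnH-psbA : ITS, the ratio of the observed per-locus mean
  interspecific distances), root depth 0.0035 substitutions/site at the
  slowest-locus scale, intraspecific depth 1.5e-4, ~11 indel events of 1–25
  columns on trnH-psbA and ~5 of 1–2 on ITS, and two samples of one species
  missing the rbcL and matK genes. No published introgression rate exists,
  so the preset defaults to none; capture scenarios set it explicitly.

All draws flow from one seeded generator with named substreams per stage
(tree / assignment / genealogy / sequence / indel / introgression), so a
fixed seed reproduces the dataset byte for byte and partial re-runs stay
aligned.

### What the synthetic data do not show

The simulator validates the *machinery*, not field performance. It omits
alignment error (indels are placed, never inferred), rate variation across
sites, within-locus recombination, concerted-evolution artifacts in ITS,
ambiguity codes from heterozygosity or sequencing noise, and any
introgression mechanism beyond sister-pair capture. Perfect scores under
the known-truth configuration therefore demonstrate correctness of the
estimators and criteria, not that any real locus will discriminate real
species.

## Problem sizes

The test suite and the reproduction script use deliberately small runs:
bootstrap at 100–300 replicates (the API default is 1000), estimator
consistency at 100 replicates of 10 kb, exhaustive NJ checks at ≤ 6 taxa
(all 15 + 105 topologies), and brute-force verdict comparisons on a few
hundred random matrices. These sizes give stable statistics while keeping a
full run in seconds to minutes on one CPU.

## Known limitations

- The indel-event definition may split what DnaSP would merge when events
  from different branches abut with identical gapped sets; counts on real
  data can differ slightly from published DIP counts.
- MEGA's exact handling of ambiguity codes inside K2P counts is
  undocumented; this package excludes such columns pairwise.
- NJ tie-breaking is deterministic but arbitrary; on matrices with exact
  ties (identical sequences) the resolved topology is a convention, and
  only bipartition-supported conclusions should be interpreted.
- Only NJ trees are built; likelihood and Bayesian tree methods are
  external tools and out of scope, as are alignment, model selection, and
  any statistical test on gap overlap.
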
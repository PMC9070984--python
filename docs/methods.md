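# Methods

This note documents the models and procedures implemented in `phagewo`, the
defaults they use, and what the synthetic-data tests do and do not
demonstrate.

## Input contract

The pipeline consumes an *aligned* multi-FASTA of equal-length *orf7*
sequences plus a tab-separated host table (id, species, family, strain_st,
wsp_allele, supergroup). Alignment is an input contract: the package never
aligns, and unequal-length input is an error. All coordinates are 1-based,
inclusive alignment columns. Hosts whose MLST sequence type could not be
resolved are retained as pseudo-strains keyed by (species, *wsp* allele), so
they can still anchor transfer events; events whose strain contrast rests
only on pseudo-strains are flagged `st_unresolved` rather than dropped.

## Pseudogene filtering

An *orf7*-like sequence is a pseudogene when, read in the dataset's reading
frame with its own gaps removed, it contains TAA/TAG/TGA strictly before its
final complete codon. The frame is chosen automatically as the first frame
(1–3) in which the column-majority consensus is stop-free; because the
amplicon is an internal gene fragment, a stop in the final codon does not
disqualify a sequence. Pseudogenes are excluded from typing and every
downstream stage but retained in reports. If no frame yields a stop-free
consensus the filter refuses to guess and asks for a manual frame.

## Distances and typing

Pairwise distances use the Kimura 2-parameter model with pairwise deletion:
columns where either sequence carries `-` or `N` are dropped; over the
remaining `n_eff` sites, `P` = transition proportion, `Q` = transversion
proportion, and `d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]`. When the log argument is
non-positive the pair is saturated: `d` is recorded as undefined (infinite),
which compares greater than any threshold and therefore never merges.

A phage WO type is a cluster of functional sequences at
`type_threshold = 0.015` (1.5% divergence; equivalently >= 98.5% identity —
an uncorrected-identity mode, `identity_mode="p_identity"`, is provided and
agrees with the K2P mode in the small-distance regime where K2P ≈ p).
Linkage is genuinely underdetermined by a bare threshold, so both semantics
are implemented:

* `single` (default): connected components of the `d <= τ` graph. This
  reproduces "identical or one-substitution" groupings conservatively;
  chained intra-type pairs exceeding τ are possible and are surfaced by
  `intra_type_violations` rather than hidden.
* `complete`: agglomerative complete linkage cut at τ, guaranteeing every
  intra-type pair satisfies the threshold.

Output is deterministic: types ordered by (size desc, first-seen member id),
named `WO` + host abbreviation (genus initial + first two epithet letters,
overridable) + index; a species with exactly one type gets the bare name.
`scope="per_species"` names and counts types within each host species;
`scope="global"` clusters all species jointly (the mode transfer detection
needs) while keeping species-local names as cross-references.

## Transfer enumeration

One transfer event = one global type whose members span >= 2 distinct strain
keys, regardless of how many species carry it. No directionality is
inferred. Each event records its strains, species, per-member supergroup
multiset, a cross-supergroup flag (both A and B present), and the minimum
inter-strain K2P distance. A strict near-identity tally
(`strict_identity_transfers`, <= 1 raw mismatch) is emitted alongside the
cluster-threshold tally because the two published criteria (1.5% clusters
vs. "identical or one base substitution") need not coincide.

## Recombination detection

Within each species with >= 3 functional types, all
child-in-unordered-parent-pair triplets of type representatives are scanned
(n types give n·C(n-1,2) triplets). An *informative site* is a column where
the parents differ and the child matches exactly one of them.

* **MaxChi** — for each parent, the child/parent match vector over
  triplet-variable sites is split at every cut between consecutive
  informative sites (the cut places all variable sites up to and including
  the flanking informative site on the left); the statistic is the maximum
  2×2 chi-square (match/mismatch × left/right), no continuity correction.
* **Chimaera** — the same cut scan on the binary parent1-vs-parent2 vector
  restricted to informative sites.
* **3Seq-style walk** — informative sites labelled +1 (matches parent 2) /
  −1 (matches parent 1); the statistic is the maximum ascent (and,
  symmetrically, descent) of the cumulative walk. The original method's
  exact hypergeometric tables are deliberately not reproduced.
* **GENECONV-like** — the best maximal run of informative sites matching
  one parent exclusively, scored as run length × column span.
* **BootScan** — sliding windows (200 columns, step 20) bootstrap the
  grouping of the child with parent 1 vs parent 2 against an outgroup
  (another type of the same species; the method is skipped when none
  exists). The 4-taxon grouping decision uses the four-point condition on
  p-distances, which for four taxa selects the same topology as
  neighbor joining. Window supports use 1,000 bootstrap replicates (the
  bootstrap size used throughout). The recombination signal is both
  partners reaching >= 70% support somewhere along the alignment; the
  statistic is min(max support for parent 1, max support for parent 2).
  Without such a supported partner switch there is no signal and p = 1.

Significance is uniform, testable machinery: seeded permutation nulls
(site/label-order shuffles for the first four methods, n_perm = 1000;
column-order permutation destroying spatial structure for BootScan,
n_perm = 100 — its null must re-run the windowed bootstrap, and 1/101
granularity is adequate against α = 0.05 at the per-species triplet counts
the scan targets). Permutation seeds derive from the triplet's member ids,
so results are reproducible and invariant to input record order. These
p-values intentionally do not reproduce the analytic p-values of the
original tools.

Consensus: per method, p-values are Bonferroni-corrected over the species'
triplet count; a triplet with >= `consensus_min_methods` (default 3)
corrected calls at `alpha = 0.05` is a candidate. Candidates sharing the
child and a begin breakpoint within ±10 columns merge into one event; the
parent appearing in the most candidates becomes the major parent, the rest
minor parents (capped at 4). Breakpoints follow the begin-column
convention; for segment-reporting methods the edge interior to the
informative range is used (an edge-touching parental segment's boundary is
the splice point). Triplet scans also flag *reciprocal* (mirror) events in
which a true parent appears recombinant with the child as partner; these
are reported, as published recombination tables do, rather than suppressed.
A cross-species scan exists but is off by default: recombination is sought
within the phage complement of a single host.

## Trees and congruence

Neighbor joining (scikit-bio) on K2P distance matrices, negative branch
lengths clamped to zero; maximum-likelihood tree search is deliberately out
of scope and replaced by NJ + bootstrap, which the threshold-free
congruence summary does not depend on. Branch support = % of seeded column
resamples (default 1,000) whose NJ tree contains the bipartition.
Congruence between phage and symbiont trees is summarised by (a) the
normalized Robinson–Foulds distance (explicit bipartition sets, so
multifurcations are handled naturally) between the symbiont tree and the
phage tree collapsed to strain labels (first leaf per strain kept), and
(b) the tanglegram crossing candidates: phage types that have a same-strain
companion in the tree yet whose nearest neighbor (patristic distance) maps
to a different strain. Under vertical co-divergence each strain's types
form their own clade and the list is empty; the companion requirement keeps
singleton strains from crossing vacuously.

## Synthetic data

The generator emulates the survey's structure at desk scale: five butterfly
species, one *Wolbachia* strain each (two strains shared across species;
supergroups A and B both present), 3–4 phage types per species, three
members per type. Sequences evolve from a stop-free root ORF under K80
(transition/transversion rate ratio κ = 2), the model whose distance the
typing stage assumes — distance estimation is unbiased by construction.
Substitution events are Poisson (multiple hits allowed; the K2P estimator
corrects for them), and functional lineages are rejection-sampled to stay
stop-free. Defaults: 399 columns (the amplicon scale, divisible by 3 so
the in-frame stop machinery is well defined), within-type divergence 0.003,
between-type divergence 0.08 (either side of the 0.015 threshold, as the
type definition requires), one transfer (donor ancestor copied into a
different-strain species before member noise, yielding the
identical-or-one-substitution cross-strain signature), one recombinant
(parent ancestors spliced at a codon-aligned breakpoint, drawn uniformly
from the central third unless given), and two pseudogenes (one internal
TAA introduced into members of real types — so they would co-cluster with
their source type if the filter missed them). Everything is seeded and
byte-reproducible.

What passing recovery tests shows: the pipeline's statistics recover
planted structure under the model they assume, at realistic divergences.
What they do not show: robustness to indels and alignment error (no indel
simulation), rate heterogeneity or selection (none simulated), primer or
cloning artifacts, or the sampling depth effects of real clone libraries.

A note on clonal negatives: under star-shaped clonal evolution a lineage's
substitutions occasionally cluster spatially by chance, and cut-scan
statistics legitimately detect that heterogeneity; with the per-species
Bonferroni correction this yields consensus events in about 0.5–1% of
no-recombination species-replicates — the unit at which the correction
controls error.

## Problem sizes and numerical choices

The recovery study uses 20 seeds of the default configuration (56 sequences
per dataset, ~30–60 triplets) plus 20 clonal seeds; chi-squares carry no
continuity correction; permutation p-values use the add-one estimator
(1 + #{null >= obs}) / (1 + n_perm); ties in 4-taxon grouping resolve to
the first pairing; undefined distances never merge and abort tree building
with the offending pair named.

## Known limitations

* Permutation p-values are exchangeability-based and will not numerically
  match analytic p-values of the original detection tools; only the
  count-based consensus is comparable.
* Single-linkage typing can chain through intermediates; the violations
  report makes this visible but the type counts still depend on linkage in
  dense clusters.
* BootScan needs >= 4 types in a species to have an outgroup; with exactly
  3 types the consensus effectively runs over 4 methods.
* The breakpoint estimate is the median of per-method begin estimates; for
  breakpoints near alignment ends the segment-edge disambiguation can be
  off by the local informative-site spacing.
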
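# Methods

## Distance model

All pairwise distances are substitution-model corrections of per-pair
difference counts over *comparable* sites: alignment columns where both
residues are unambiguous DNA (A/C/G/T). Gap, N and IUPAC-ambiguity columns
are deleted **pairwise** — per pair, not per alignment — because complete
deletion discards information for every pair whenever any single sequence
has a gap, and barcode libraries routinely contain a few truncated
sequences. Ambiguity codes are treated as incomparable rather than
fractionally counted; this keeps counts integral and the computation
deterministic.

* **p-distance**: (s + v) / n, with s transitions, v transversions, n
  comparable sites.
* **K2P**: d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), P = s/n, Q = v/n. The
  standard choice for low-divergence barcode data.
* **TN93**: separates purine (s1, A↔G) and pyrimidine (s2, C↔T)
  transitions and weights terms by empirical base frequencies, here the
  arithmetic mean of the two sequences' frequencies over the pair's
  comparable sites. TN93 collapses onto K2P when frequencies are equal and
  s1 = s2; this limit is verified to 1e−9 in the tests. TN93 backs the
  substitution-saturation table (transitions and transversions per pair
  against the corrected distance, with least-squares slope and R² as the
  linearity summary), mirroring how saturation is conventionally screened
  before using a marker.

**Undefined distances.** When n = 0 or a logarithm argument is ≤ 0
(saturation), the distance is undefined: stored as NaN, listed in
`DistanceMatrix.undefined_pairs`, excluded from every average with a
warning, and rejected outright by tree building. Treating saturation as
"very large" instead would silently poison means and minima.

## Neighbor joining and species clusters

Trees summarize the distance matrix (they are clustering diagrams, not
phylogenetic hypotheses). The Saitou–Nei agglomeration is delegated to
scikit-bio; taxa are fed in lexicographic id order so results are invariant
to input ordering, and negative branch-length estimates are clamped to
zero (the library's behavior; only branch lengths, never the topology, are
affected). A species is a *single cluster* when some edge of the unrooted
tree bipartitions exactly its leaves from everything else; singletons
count as single clusters. Monophyly is assessed on bipartitions, so the
choice of display root is irrelevant. No bootstrap is computed.

## Divergence summaries

Per species (≥ 2 sequences): mean pairwise intraspecific distance, theta
(numerically identical at the species level; the two diverge only in how
they are averaged upward — theta averages species means unweighted, the
"average intraspecific distance" of a genus weights every pair equally)
and coalescent depth (maximum intraspecific distance). Per genus or tribe
(≥ 2 species): mean over all between-species sequence pairs, with both the
SD (ddof = 1) and the SE of the pair distances, since published tables are
inconsistent about which "±" they print.

The **gap report** pools intraspecific and interspecific distances and
classifies the interval between max-intra and min-inter: *overlap* when
max-intra > min-inter, otherwise *gap* (a coincident boundary is a
zero-width gap). Histograms use a default bin width of 0.005
substitutions/site, the granularity at which barcode-gap histograms are
usually drawn; it is configurable.

**Synonym pruning** flags congeneric species pairs whose mean
between-species distance is strictly below 0.002 (likely synonyms that
would otherwise contaminate identification statistics); both members of a
flagged pair are removed from the filtered label map. Strict inequality at
the boundary, both-removal, and the congeneric restriction are all
configurable readings of an underdetermined convention.

## Identification criteria

Both criteria are leave-one-out over the library. Best match: success iff
every reference at the minimum distance shares the query's species; ties
across species are ambiguous; otherwise misidentified. Best close match
adds a threshold — the distance below which 95% of all pooled
intraspecific distances fall — and leaves queries with no reference within
it unidentified. Four categories are reported (success / ambiguous /
misidentified / unidentified); a compatibility mode folds unidentified into
ambiguous for comparison with three-row summaries.

Two numerical choices matter:

* **Quantile rule**: the threshold uses the empirical order statistic
  (`inverted_cdf`) — the smallest observed distance covering the requested
  fraction — which is the literal reading of "the value below which 95% of
  distances fall". Linear interpolation is available via `method=`.
* **Tie detection** uses exact floating-point equality (tolerance 0 by
  default, configurable). Identical site patterns give bit-identical
  distances, so real ties are detected exactly; an epsilon would instead
  convert near-misidentifications into ambiguities.

## The tag-barcode method

For each species with at least `min_seqs` (default 3) sequences, the
variability of every column is the fraction of that species' unambiguous
residues differing from the within-species modal residue (modal ties broken
alphabetically; gaps and ambiguity codes excluded from numerator and
denominator). Positions with variability strictly above the threshold
(default 0.30) form the species' tag. Tags are reported 1-based on the
standard barcode coordinates and round-trip through a TSV. Below 10
sequences a warning marks the tag as imprecise — with few haplotypes the
variability estimate is noisy — but small species remain usable.

Tag-adjusted computations follow one consistent rule: a distance involving
candidate species *S* as the *within*-species frame drops *S*'s tag
columns; between-species distances never drop columns. Concretely:

* `tag_adjusted_intra`: species S's intraspecific distances are recomputed
  on the alignment minus S's tag; other species' tags are irrelevant to S.
* `tag_adjusted_inter`: a definitional pass-through — interspecific
  distances are bit-identical before and after tagging.
* `tag_best_close_match`: leave-one-out re-evaluation after tagging. Every
  query is scored against every species, with each candidate species
  compared on the alignment minus its own tag, at a threshold re-derived
  from the tag-adjusted intraspecific distances. No shortlist is applied:
  this is the retrospective before/after comparison of the whole library,
  and a shortlist based on unadjusted distances would freeze exactly the
  failures the method is meant to repair.
* `tag_identify`: the prospective workflow for unknown (aligned) queries:
  first shortlist species whose nearest reference lies within the
  unadjusted threshold, then rescore against each shortlisted species with
  its tag removed at the adjusted threshold. The shortlist threshold is
  configurable (pass `inf` to disable).

## Synthetic data generator

The generator emulates a multi-species mitochondrial barcode library: a
star phylogeny per genus (genus ancestor drawn i.i.d. from stationary base
frequencies, default 36% A / 13% C / 10% G / 41% T, i.e. ~75% A+T), species
ancestors evolved along branches of `target_inter / 2` expected
substitutions per site, individuals along `target_intra / 2`. Sites evolve
independently under the exact K2P transition-probability matrix at the
configured transition/transversion ratio (default 2.0), so the K2P
estimator is correctly specified and parameter recovery is a fair test:
the expected distance between conspecifics is `target_intra` and between
congeners `target_inter + target_intra`. Defaults (10 species × 10
individuals, 658 bp, intra 0.01, inter 0.10) represent a well-sampled,
well-separated library.

Hypervariable columns are injected post hoc: within each designated
species, chosen columns are overwritten so the non-modal residue fraction
equals `hv_variability` (non-modal states spread over the three alternative
bases; feasible up to 0.75). Every injected column is recorded in a JSON
ledger with its realized variability. `hv_individuals` optionally
under-samples the hypervariable species, reflecting that problem species
are often the sparsely collected ones; it also controls what fraction of
the pooled intraspecific distances the inflated pairs contribute, which
determines whether the 95% threshold absorbs them.

What the generator does **not** emulate: indels and alignment error (the
alignment is gap-free; gap handling is exercised by hand-built fixtures),
coalescent genealogies and shared polymorphism, rate variation across
sites or lineages, nonstationary composition, and sequencing error.
Passing tests therefore show that the method behaves as designed when its
assumptions hold — hypervariable columns really are species-internal noise
— not that real libraries meet those assumptions.

## Problem sizes and reproducibility

Test and acceptance workloads are sized for interactive runs: 50 random
additive matrices (6–10 taxa) for the neighbor-joining oracle, 100 random
12-sequence fixtures for the identification oracle, one pinned 100-sequence
library for parameter recovery, and seeded replicates of a 222-sequence,
20-species library (three under-sampled species carrying 10 injected
hypervariable columns at variability 0.5) for the tag-method
direction-of-effect checks. Every stochastic component takes an explicit
seed; fixed seeds give byte-identical FASTA output and byte-identical
pipeline TSVs (floats printed at 6 significant digits).

## Known limitations

* Gamma rate heterogeneity, codon-position models and model selection are
  out of scope; K2P/TN93/p are the only distances.
* Tag discovery needs several individuals per species; with fewer than ~10
  haplotypes tags are noisy, and with fewer than `min_seqs` a species gets
  no tag at all (it can still be identified, just not tag-adjusted).
* The tag rule assumes hypervariable columns are species-internal noise;
  if a column is hypervariable in one species but diagnostic between two
  others, removing it for the first species cannot hurt the others (their
  comparisons keep the column), but the method cannot rescue species whose
  overlap is caused by genuinely low interspecific divergence (near
  synonyms) — those are flagged by the 0.002 pruning rule instead.
* Monophyly assessment ignores branch lengths and support; a species split
  by a zero-length edge counts as split.
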
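# tagbarcode

Distance-based DNA-barcode evaluation and species identification for
multi-species reference libraries, including **tag barcodes**: a method that
removes the overlap between intra- and inter-specific divergence
distributions by discovering per-species hypervariable alignment positions.

## The problem

A DNA barcode library assigns unknown specimens to species by sequence
distance against labeled reference sequences (mitochondrial markers such as
COI, COII or Cytb in insects). Identification works when a *barcoding gap*
separates the distribution of within-species (intraspecific) distances from
the distribution of between-species (interspecific) distances. In many
groups — AT-rich insect mitochondria are a classic case — a few species
carry *hypervariable sites*: alignment columns where more than 30% of a
species' own individuals differ from the species consensus. These columns
inflate intraspecific divergence without helping to separate species, the
two distributions overlap, and distance identification turns ambiguous.

The tag-barcode method attaches to each species a **tag**: the sorted list
of its hypervariable positions (1-based, on the standard barcode
coordinates). The rule is deliberately asymmetric:

* intraspecific distances of species *S* are recomputed with *S*'s tag
  columns **removed** (shorter sequences, lower divergence);
* interspecific distances always **retain** every column, so they are
  bit-identical to the unadjusted values.

Removing only the within-species noise restores the gap and raises
best-close-match identification success.

## What is implemented

| module | contents |
| --- | --- |
| `tagbarcode.seqio` | aligned FASTA + metadata TSV I/O, `BarcodeAlignment` |
| `tagbarcode.distance` | substitution counting, K2P / TN93 / p distances with pairwise deletion, distance matrices, substitution-saturation tables |
| `tagbarcode.njtree` | neighbor joining (via scikit-bio), Newick output, species-cluster (monophyly) status |
| `tagbarcode.divstats` | base composition and site classes, per-species and per-group divergence tables, barcoding-gap reports, synonym pruning |
| `tagbarcode.identify` | leave-one-out best match and best close match with the 95% intraspecific threshold |
| `tagbarcode.tags` | tag discovery (>30% within-species variability), tag-adjusted divergences, tag-aware identification |
| `tagbarcode.synth` | synthetic barcode-library generator with controlled divergences and injectable hypervariable columns |
| `tagbarcode.cli` | `tagbarcode` command with `simulate`, `distances`, `tree`, `divstats`, `identify`, `tags`, `gap`, `pipeline` |

The Kimura two-parameter distance is computed as

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions over the pair's
comparable sites; TN93 additionally separates purine (A↔G) from pyrimidine
(C↔T) transitions and uses empirical base frequencies. Sites where either
sequence has a gap, N or an IUPAC ambiguity code are deleted pairwise.
Distances outside the model domain (saturation) are flagged undefined and
excluded from averages, never silently zeroed.

Best match assigns each query (leave-one-out) to the species of its nearest
reference; equally-near references from two or more species are ambiguous.
Best close match additionally leaves queries unidentified when the nearest
reference lies above the distance below which 95% of all intraspecific
distances fall.

## Worked example

Simulate a 20-species library (12 individuals each, 658 bp, AT-rich) in
which three under-sampled species (6 individuals) carry 10 injected
hypervariable columns, then run the full pipeline:

```sh
tagbarcode simulate --seed 11 --species-per-genus 20 \
    --individuals-per-species 12 --hv-individuals 6 --length 658 \
    --target-intra 0.002 --target-inter 0.05 \
    --hv-species G01_sp01,G01_sp02,G01_sp03 --hv-n-columns 10 --out sim
tagbarcode pipeline --fasta sim/alignment.fasta --metadata sim/metadata.tsv --out run
```

which prints

```
222 sequences; realized intra=0.0027 inter=0.0555
best match success 100.0% | best close match success 92.8% (threshold 0.0076) | tag-adjusted success 99.5% (threshold 0.0061) | gap gap -> gap
```

Reading: the generator realized the requested divergences (mean
intraspecific K2P 0.0027 vs mean congeneric interspecific 0.0555). Best
match is perfect, but best close match leaves 7.2% of queries unidentified:
the hypervariable species' sequences sit farther from their own
conspecifics than the 95% intraspecific threshold (0.0076). After tag
discovery (`run/tags.tsv` lists each species' positions, e.g.
`G01_sp01: 43,48,103,118,211,308,323,384,418,474` — exactly the injected
columns), distances to each candidate species are recomputed without that
species' tag, the threshold is re-derived from tag-adjusted intraspecific
distances (0.0061), and success rises to 99.5%. Interspecific distances are
unchanged throughout. `run/summary.json` and the per-query outcome tables
hold the same numbers in machine-readable form.

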
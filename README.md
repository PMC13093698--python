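# nanofish

Desk-scale Nanopore 12S eDNA metabarcoding, end to end: from raw
dual-barcoded MiFish-U amplicon reads to a curated species-by-sample table
and the community statistics used in reef-fish biodiversity monitoring.

Environmental DNA (eDNA) metabarcoding censuses a fish community by
amplifying a short taxonomically informative marker — here the ~170 bp
hypervariable fragment of the mitochondrial 12S rRNA targeted by the
MiFish-U primer pair — from filtered seawater and sequencing the pooled,
per-sample-barcoded amplicons on an Oxford Nanopore device. The audience is
ecologists and bioinformaticians who want a transparent, dependency-light,
fully deterministic implementation of that workflow: every external binary
of the field pipeline (demultiplexer, greedy clusterer, polisher, BLAST) is
replaced by an internal, tested equivalent, and a read simulator provides
ground truth so each stage can be scored exactly.

## What it computes

- **Read front end** — reads are kept when their aggregate quality exceeds
  Q10 (aggregated as −10·log₁₀ of the mean per-base error probability) and
  their barcode-trimmed length falls in 180–250 bp; a read is assigned to a
  sample only when the *same* barcode is found at both ends (≥85% identity),
  which suppresses between-sample chimeras; primers are located by edit
  distance and the insert reoriented to the forward strand.
- **Two-round OTU clustering** — greedy incremental clustering against
  cluster representatives at a fixed identity threshold, with identity
  defined as identical aligned positions over the shorter sequence length;
  each cluster is reduced to a majority-rule consensus; consensuses from all
  samples of an experiment are re-clustered at 97% into OTUs counted across
  samples.
- **Taxonomy** — exact affine-gap Smith–Waterman (match +2, mismatch −3,
  gap 5/2) against a taxonomy-annotated reference panel, normalized to
  Karlin–Altschul bit scores *S′* = (λ·S − ln K)/ln 2 with λ = 0.625,
  K = 0.41. References with byte-identical amplicons collapse into composite
  labels ("Pomacentrus pavo-coelestis"). Species rows whose read-weighted
  mean bit score falls below 250 pool into a single "unknown" row.
- **Curation** — control taxa (human, positive control) are stripped;
  contaminants are flagged by a one-sided Fisher exact test on their
  prevalence in field/PCR blanks versus environmental samples (flagged when
  the score is below 0.5); counts are rarefied without replacement to 90% of
  the smallest environmental sample.
- **Ecology** — observed richness, Shannon, Simpson and bias-corrected
  Chao1; Jaccard distances on presence/absence; PCoA; PERMANOVA with
  sequential sums of squares for `habitat * season` designs; beta-dispersion;
  species-accumulation curves with a log-model effort threshold (the number
  of replicates beyond which one more sample adds less than one species);
  Mann–Whitney, Kruskal–Wallis with Dunn/Holm post hoc tests; nocturnal
  read/species ratios for diel designs; and an eDNA-versus-visual-census
  method comparison.
- **Simulator** — synthetic reference panels with controlled pairwise
  identity and optional byte-identical species pairs, dual-barcoded noisy
  reads (independent substitution/insertion/deletion errors, chimeras, human
  contaminants), experimental designs with blanks and positive controls, and
  a ground-truth table per read. An aquarium method-comparison dataset
  (six eDNA samples plus a visual census of the same tank) ships with the
  package.

## Worked example

```sh
python examples/03_aquarium_comparison.py
```

prints

```
taxa detected by eDNA only : 14
taxa detected by both      : 16
taxa seen visually only    : ['Pomacentrus pavo']
mean relative abundance, shared taxa    : 5.67%
mean relative abundance, eDNA-only taxa : 0.66%
```

eDNA recovered every visually recorded species — the single visual-only
label is a congener whose reads are hidden inside the composite
`Pomacentrus pavo-coelestis` 12S label — and detected 14 additional taxa,
but those extras average an order of magnitude fewer reads (0.66%) than
species confirmed by both methods (5.67%), so read abundance carries real
quantitative signal.

The other examples simulate a run and push it through the front end
(`01`), cluster and assign simulated inserts (`02`), run the statistics
battery on a two-habitat design (`04`), and execute the whole pipeline with
a manifest proving byte-level reproducibility (`05`). A thin CLI wraps the
same library calls:

```sh
nanofish run-all --seed 11 --outdir out/
```

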
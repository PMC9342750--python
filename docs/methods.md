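# Methods

## Overview

`hallmarkmap` reconstructs, as a reusable pipeline, a membrane-proteome
hallmark analysis: proteins annotated with GO biological-process terms are
binned into ten cancer-hallmark categories, mass-spectrometry evidence is
quality-filtered into a detected set with spectral-count abundances, genes
are summarized per chromosome arm, detected membrane hallmark proteins are
cross-referenced against cancer-gene and drug-target catalogues, and a
confidence-thresholded protein–protein interaction (PPI) network is
analyzed for degree and betweenness centrality to rank putative drug
targets.

## Hallmark assignment

Each hallmark is a flat list of GO biological-process term labels. A term
printed with an "(& regulation)" qualifier is matched together with exactly
three regulation forms — `regulation of X`, `positive regulation of X`,
`negative regulation of X`. No GO-graph descendant closure is performed:
the reference queries were flat controlled-vocabulary searches, and exact
normalized-label matching (case-folded, whitespace-collapsed) is the
closest reproducible proxy. This deliberately prevents substring artifacts
such as "cell death" capturing "programmed cell death". When both a
definition term and an annotation carry a GO identifier, identifiers take
precedence over labels. Compound printed entries in the source vocabulary
are split into plain terms, and the genome-instability "disease variant"
marker is carried as a boolean annotation column rather than a GO term.
Some terms appear under two hallmarks (autophagy; cellular response to
hypoxia; signal transduction by p53 class mediator), so multi-membership
is an intended property, not an error: a protein annotated only with
"autophagy" belongs to both the immune-destruction-evasion and
apoptosis-evasion hallmarks.

## Evidence filtering

Identification quality follows the upstream search conventions: at least
two unique peptides per protein (`min_unique=2`), rank-1 peptides only, and
an FDR class within the requested ceiling. FDR is categorical — strict
(0.01) or relaxed (0.03) — attached by the search engine; target–decoy
statistics are out of scope and never recomputed. Abundance is
`log10(summed SC)` where the sum pools every (enrichment method, replicate,
injection) spectral-count cell; a protein passing the identification
filters with zero total spectra is treated as a data inconsistency and
raises. Display scaling clamps `log10(SC)` to [0, 5] rather than rescaling;
the lower observable bound for a two-spectrum protein is log10(2) ≈ 0.301.

## Genome mapping

Coordinates are 1-based inclusive (Ensembl convention). Arm assignment
compares the gene start with the centromere midpoint; centromere-spanning
genes go to the arm of their start (a deterministic tie-break for a rare
degenerate case). A default chromosome model (GRCh38 lengths, approximate
centromere midpoints, acrocentric flags for 13/14/15/21/22) ships as an
overridable data file. Detected genes without a locus are reported in an
unmapped sidecar, never dropped. Per-hallmark percentages may sum above
100 per the multi-membership convention. Track export emits plain
whitespace-delimited `chromosome start end value` text ordered by
(chromosome, start); rendering the circular graphic is out of scope.

## Catalogue cross-referencing

Gene symbols match exactly after upper-casing, with an optional two-column
alias table for synonyms. Dual-role genes (oncogene and tumor suppressor)
form a third role class and are never double-counted, so role counts
partition the matched set. The representative analysis set is the union of
catalogue-matched genes and literature-reported hallmark proteins; genes in
both sources keep catalogue provenance. Venn-region counts are computed
per element and always sum to the union cardinality.

## PPI network analysis

Edges carry confidence scores in [0, 1]; the STRING-style integer 0–1000
dialect is auto-detected per file and divided by 1000 on read. Scores act
only as a construction filter (default threshold 0.9, "very high"
confidence; 0.7 = "high"); geodesics are unweighted. The supplied node set
is preserved, so proteins with no confident partner remain isolated nodes.

Betweenness is computed in-package by Brandes' algorithm — per-source BFS
with geodesic counting and reverse accumulation of pair dependencies — and
normalized by 2/((n−1)(n−2)) with n the **full** node count including
isolated nodes, matching the convention of desktop network-analysis tools
that report centralities alongside graphs carrying unconnected nodes.
Graphs with fewer than three nodes return all zeros (the normalization is
undefined). Whether per-component normalization was intended in the
reference workflow is unknowable; the whole-graph convention is the
recorded choice. The test suite cross-checks the implementation against
both an exhaustive simple-path enumeration oracle on ≤7-node graphs and an
independent library implementation.

Network statistics take an explicit `node_scope` switch (`all` vs
`degree_ge_1`), because summary statistics over a node list with isolates
and over the connected portion are both legitimate and materially
different; the scope used is recorded in the output. Characteristic path
length averages over connected ordered pairs only (disconnected pairs are
ignored, never replaced by infinity or n), diameter and radius are taken on
the largest connected component, mean clustering counts degree<2 nodes as
zero, and edgeless graphs report path metrics as explicit null markers.

The power-law check fits log10(frequency density) on log10(degree) by
least squares over **geometric (logarithmic) degree bins**. Raw
per-degree fits on heavy-tailed data are dominated by the long run of
one-count degrees and systematically underestimate the exponent (simulated
at ≈1.8–2.0 on 2000-node preferential-attachment graphs whose true
exponent is 3); log-binning averages the tail and recovers ≈2.7–3.0. The
estimator falls back to the raw fit when the degree span yields fewer than
three bins, and refuses graphs with fewer than three distinct degrees.

Target prioritization reports known targets with degree ≥ 1, the count in
the upper third of the degree range (cutoff = max degree / 3 over
degree≥1 nodes; a 2/3-quantile alternative is available), full rank lists
by degree and by betweenness with ties broken by node identifier, the
number of nodes with positive betweenness, and non-target nodes above a
degree cutoff (default 6) as candidate novel targets.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; it
is a study-condition definition, not a calibration to any particular cell
line.

- **Proteome** (default n = 5,000): hallmark multiplicity per protein is
  drawn from a configurable distribution (default mean ≈ 1.7, mass on
  0–10); the chosen hallmarks emit 1–2 terms each from the expanded term
  pools, plus Poisson(1) decoy terms matching no hallmark. Membrane flags
  are Bernoulli(0.4), mirroring the ~35–40 % membrane fraction of coded
  genes. Because hallmarks share terms, the recorded ground-truth
  membership is the set *implied by the emitted terms*, recomputed at
  generation time with a brute-force double loop that is independent of the
  assignment code it later validates.
- **Evidence**: latent log10 abundance ~ Normal(1.5, 0.8); detection
  probability is logistic with slope 2 around midpoint 1.5; detected
  proteins receive zero-truncated unique-peptide counts and
  negative-binomial spectral counts (dispersion 2) across
  3 methods × 2 replicates × 2 injections, with at least one spectrum
  guaranteed. Undetected proteins are absent, as in real search output.
- **PPI** (default 200 nodes): Barabási–Albert growth with attachment 2;
  five planted hubs drawn from the late (ordinarily low-degree) half of the
  growth order each receive 30 extra random attachments — chosen so hub
  degree exceeds the expected natural maximum (~2·√n ≈ 28), making
  degree-based hub recovery a statement about the planted signal. Scores
  come from a two-component uniform mixture so thresholding at 0.9 retains
  on average half the edges.
- **Tables**: loci are uniform over non-centromeric regions (1 Mb margin),
  never on acrocentric p-arms and never on chromosome Y (the modeled cell
  line is female-derived); roles follow (0.5, 0.3, 0.2)
  oncogene/suppressor/dual fractions, tier 1 with probability 0.8; planted
  hubs are drug targets with probability 0.8 versus 0.05 background; 31
  literature genes are sampled from hallmark-positive proteins.

One global seed drives independent per-module substreams
(`default_rng([seed, stream])`), so any table regenerates in isolation and
identical seeds give byte-identical files.

What the generator does **not** emulate: real GO annotation sparsity and
bias, peptide sequences and spectra, protein-group parsimony, STRING score
structure, aneuploidy, or correlated detection across enrichment methods.
Passing tests therefore demonstrate internal correctness of the pipeline's
logic under a known generative model — not that any specific biological
count from a real proteome would be reproduced.

## Determinism and output conventions

All tabular output is TSV with fixed column order and UNIX newlines; JSON
uses sorted keys; floating-point cells are rounded at write time
(centrality to 9 decimals). The run manifest records input SHA-256
checksums, analysis parameters and the tool version; identical manifests
imply identical result files.

## Problem sizes

The shipped verification suite uses 200–500-protein tables for oracle
comparisons, 2,000 genes for genome summaries, ≤7-node graphs (200
replicates) for exhaustive centrality enumeration, a 2,000-node graph for
the power-law fit, and the default 5,000-protein / 200-node bundle with 100
seeded PPI replicates for end-to-end recovery — sizes chosen so the whole
suite completes in well under a minute while keeping Monte-Carlo bounds
(3 standard errors) meaningful.

## Known limitations

- Exact-label matching cannot recover annotations phrased with synonyms or
  deeper GO descendants; ontology closure is an extension point.
- The centromere midpoints in the default chromosome model are approximate
  (megabase resolution); arm percentages near the centromere inherit that
  imprecision.
- Characteristic path length over connected pairs only is not comparable
  across graphs with very different fragmentation.
- Betweenness normalization by the full node count makes values from
  differently-sized node universes incomparable; use the `degree_ge_1`
  scope consistently when comparing connected subsets.
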
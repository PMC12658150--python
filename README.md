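# tssmut

Sequence-context-corrected mutation-density analysis around transcription
start sites (TSS), for population-genetics and mutation-rate researchers
who want to quantify localized germline or somatic mutation-rate structure
— promoter hotspots, strand asymmetries, selection footprints — from
variant calls, gene models and a reference genome.

## The model

Mutation counts are compared against a genome-wide k-mer sequence-context
expectation.  For pentanucleotide context *i* and alternate allele *j*,

```
m_ij = ( Σ_l n_ij^l ) / a_i
```

where `n_ij^l` counts mutations of type (i, j) at site *l* over the
analysed site universe and `a_i` is the abundance of context *i* among
those sites, read on the coding strand of the gene owning each site.  The
relative mutation density of window *b* of gene *t* is

```
μ_tb = observed_tb / Σ_{l∈b} Σ_j m_{c_l j}
```

and `μ′_tb = μ_tb / g_t`, where `g_t` is the observed/expected ratio of
the entire gene's considered regions, removes regional (replication-time
scale) rate variation.  Bin-level values are site-weighted means across
genes with gene-resampling bootstrap intervals.  On top of this core sit:

- **windows** — TSS/TTS-anchored, transcription-oriented, non-overlapping
  windows with proximity splitting, nearest-anchor resolution of
  intergenic overlaps, multigene-transcription exclusion and BED masks;
- **signatures** — abundance-rescaled NNLS decomposition of 96/192-channel
  profiles with thresholding, downsampling and minor-weight aggregation;
- **regression** — Poisson / negative-binomial GLMs of window counts with
  log-expected offsets, sum-coded position interactions, GVIF
  multicollinearity filtering, dispersion diagnostics and single-step
  max-|z| adjusted contrasts;
- **selection** — windowed dN/dS `r(b) = (Σd^z/Σh^z)/(Σd^s/Σh^s)`,
  allele-frequency density ratios and GC-biased gene-conversion strata;
- **strandbias** — replication-direction calling from timing profiles and
  transcription × replication strand-stratified densities;
- **genesets** — exact conditional binomial TSS-vs-rest rate-ratio tests
  for gene sets and per-gene scans;
- **simulate** — a synthetic-data generator that plants known hotspots,
  signature mixtures, strand asymmetries and selection, so every statistic
  has a ground truth.

## Worked example

`examples/01_hotspot_density.py` simulates 200 genes with a planted
1.5-fold mutation excess within 1 kb of every TSS and recovers it:

```
simulated 30354 mutations on 200 genes
conservation check: observed 21073 vs expected 21073.00

mu' around the TSS (point = bootstrap mean, 90% CI):
  downstream bin  1: 1.505  [1.420, 1.589]
  downstream bin  2: 0.896  [0.822, 0.972]
  ...
    upstream bin  1: 1.452  [1.350, 1.541]
```

The conservation line is the algebraic identity of the context model: the
expectations summed over the matrix-estimation sites reproduce the
observed total exactly.  Bins ±1 recover the planted 1.5-fold excess;
other bins scatter around 1 (slightly below, because the hotspot inflates
each gene's `g_t`).  The other examples demonstrate signature
decomposition (`02`), covariate regression with interaction contrasts
(`03`), dN/dS under planted selection (`04`), and strand bias plus
gene-set scans (`05`).

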
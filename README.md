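# ptcore

Integrative analysis of chromatin accessibility, clusters of
cis-regulatory elements (COREs) and genome-wide cisplatin-adduct
distribution in matched drug-sensitive / drug-resistant cell-line pairs —
with a synthetic-data generator that plants known signals so every stage
of the analysis can be verified against ground truth.

## Who this is for

Labs studying how chromatin reorganisation accompanies acquired platinum
resistance (e.g. paired high-grade serous ovarian cancer lines isolated
before and after clinical resistance). The package covers the
computational side of three assays:

* **ATAC-seq** — tags are counted into 1-kb windows tiling the genome,
  RPKM-normalised, depth-filtered (mean RPKM > 1 and < 1 SD above the
  median) and tested for differential accessibility with a
  precision-weighted, empirical-Bayes moderated *t* linear model
  (|log2FC| > 2, BH FDR < 0.001). Differential windows are annotated by
  genomic class (CpG island, promoter-TSS, UTRs, exon, TTS, intron,
  intergenic) and per-class enrichment is scored with Fisher's exact test.
* **Pt-exo-seq** — cisplatin adducts are mapped by exonuclease stop
  sites: the 5' end of a read marks the platinated GpG/ApG dinucleotide.
  The read-out is (i) per-offset Fisher enrichment of platinum-target
  dinucleotides at read 5' ends (offsets −5..+10), and (ii) a windowed
  (1 kb / 900 bp sliding) log2 signal:background ratio against the mean
  of mock-treated replicates, with differential damage between lines
  called at |Δ| > 2, FDR < 0.05.
* **RNA-seq + COREs** — peaks called from merged ATAC replicates
  (local-Poisson model) are grouped into COREs (dense runs of ≥ 3 peaks
  under an adaptively chosen gap threshold), classified shared / gained /
  lost between the lines, and linked to genes with a TSS within 100 kb;
  expression shifts of linked genes are summarised by *t*-statistic
  distributions and DE-gene enrichment odds ratios.

## The statistics at the core

For a count matrix *y* (windows or genes × samples), log2-CPM values are
fitted per feature by weighted least squares with observation weights
from a lowess mean–variance trend (weight = predicted-SD⁻⁴). Residual
variances *s²_g* (df *d*) are shrunk toward a prior estimated by moment
matching of log *s²_g*:

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),   t_g = β̂_g / (s̃_g √v_g),  df = d₀ + d

with (d₀, s₀²) from digamma/trigamma inversion. Two-sided Fisher *p*
values sum hypergeometric probabilities ≤ the observed table's; rank
products use permutation *p* values; Wilcoxon rank-sum uses exact
enumeration for small samples.

## Worked example

```
python examples/04_cores_and_expression.py
```

prints, for the default synthetic pair (seed 42):

```
peaks: 1118 / 1082; gap threshold 2359 bp
COREs: sensitive 34, resistant 31; lost 14, gained 11
gained COREs: 69 genes within 100 kb, 67 differentially expressed; mean t = +5.51
  (one-sample p = 5.4e-14); DE enrichment OR = 137.09 [32.73, 574.23]
lost COREs: 96 genes within 100 kb, 85 differentially expressed; mean t = -4.83
  (one-sample p = 1.3e-13); DE enrichment OR = 42.25 [20.97, 85.16]
```

Genes near COREs *gained* in the resistant line shift toward higher
expression (positive mean *t*), genes near *lost* COREs toward lower —
the planted enhancer–expression coupling, recovered end to end from
simulated tags. The other scripts in `examples/` walk through simulation
(01), windowed differential accessibility (02), adduct mapping (03) and
the one-command pipeline (05); `ptcore run --outdir D` is the CLI
equivalent of 05.

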
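# estsurvey

Diagnostics for de novo 454/pyrosequencing EST transcriptome surveys.

When a species without a reference genome is surveyed by sequencing cDNA
libraries (expressed sequence tags, ESTs), a handful of questions decide
whether the dataset is any good, and none of them are answered by the
assembler:

* **Was sequencing exhaustive?** How many reference gene loci have been
  tagged, and how many more would another million reads discover?
* **Did library normalization work?** Duplex-specific-nuclease
  normalization flattens the abundance distribution so lowly expressed
  transcripts get "sequencing space" — but does the normalized library
  still carry quantitative expression information?
* **Why are there so many redundant unigenes?** Is the redundancy
  biological (alleles, recently duplicated paralogs) or technical
  (sequencing errors — on 454 chemistry about 1% per base, concentrated
  in homopolymer runs — frustrating the assembly)?
* **Did aggressive assembly create chimeras?** A second, more lenient
  assembly pass that *loses* reference-gene annotations has probably
  joined fragments of different transcripts.
* **What biology did each library capture?** Which functional categories
  are over- or under-represented per tissue library?

`estsurvey` implements this diagnostic toolbox as a tested Python
library with a CLI, together with a ground-truth simulator of 454-style
libraries so every stage can be validated against known truth.

## The statistics at the core

**Saturation model.** Reads are repeatedly subsampled from the pool of
gene-assigned reads; at each sample size *x* the number *y* of genes
tagged at least *k* times (*k* ∈ {1, 5, 10, 100}) is recorded and fitted
by nonlinear least squares to the hyperbola

```
y = a·x / (b + x)
```

with *a* the asymptotic number of detectable genes and *b* the
half-saturation read count. The derivative `a·b/(b+x)²` at the library's
final read count is the headline number: the expected gene yield of one
additional read. The Monte-Carlo subsampler is validated against the
exact expectation `E[y] = Σ_g P(X_g ≥ k)` with `X_g` hypergeometric.

**Redundancy classification.** Unigenes mapped to same-species reference
cDNAs are piled up column by column. A position is *identical* if every
covering unigene carries the reference base; a *putative biological
variant* if ≥ 25 unigenes share the identical point mutation, or ≥ 4
share an identical in-frame indel (length divisible by 3); a *putative
sequencing error* if it carries a point mutation below the 25-unigene
threshold or any out-of-frame indel. Variant and error flags may
co-occur, so percentages can sum to more than 100.

**Normalization assessment.** Spearman rank correlation between per-gene
read counts of library pairs; retained correlation around 0.7 means a
normalized library is flattened but still rank-informative.

**Enrichment.** Per functional category (hierarchical dotted codes, as
in MapMan bins), Fisher's exact test of a library's gene set against the
union background, Benjamini–Hochberg FDR across the categories of one
comparison, and signed z-scores (`±Φ⁻¹(1−p/2)`, so p = 0.05 ↦ 1.96) for
heatmap matrices.

## Worked example

Simulate a normalized / non-normalized leaf-library pair over 3,000
genes at 48,000 reads each, check what normalization did to the
expression ranks, and fit the discovery curve of the non-normalized
library:

```python
from estsurvey import simulate, rarefaction, saturation, library_compare
from estsurvey.gene_tagging import ExpressionProfile

cfg = simulate.SimConfig(n_genes=3000, n_reads=48000, seed=11)
prof = simulate.simulate_count_profiles(cfg)

norm = ExpressionProfile("normalized",
                         prof[prof.norm_count > 0].set_index("gene_id")["norm_count"])
raw = ExpressionProfile("non-normalized",
                        prof[prof.raw_count > 0].set_index("gene_id")["raw_count"])
r = library_compare.spearman_profiles(norm, raw)
print(f"Spearman(normalized, non-normalized) = {r.rho:.3f} over {r.n_genes} genes")

pool = rarefaction.ReadPool.from_profile(raw)
curve = rarefaction.expected_curve(pool, rarefaction.sample_size_grid(pool.n_reads, 15))
print(saturation.fit_hyperbola(curve).summary())
```

prints

```
Spearman(normalized, non-normalized) = 0.693 over 1586 genes
Hyperbolic saturation fit  y = a*x/(b+x)
----------------------------------------------
observations                    15
converged                     True
a (asymptote, genes)        2215.7  (se 116.6)
b (half-sat., reads)       20698.4  (se 2392.8)
R^2                         0.9938
final read count             48000
slope at final count        0.0097  genes/read
```

Read: the normalized library still ranks genes much like the
non-normalized one (ρ ≈ 0.69); the non-normalized pool would plateau at
~2,200 detectable genes (skewed expression keeps the rest out of reach),
and at its final depth each extra read still discovers ~0.01 new genes —
sequencing it deeper would keep paying off slowly.

The full pipeline (simulate → prep → tag → rarefy → fit → redundancy →
compare → enrich) runs from a YAML config:

```sh
estsurvey run --config survey.yaml --out-dir survey_out
```

and every stage is also available as its own subcommand (`estsurvey
prep|tag|rarefy|fit|redundancy|compare|enrich`) operating on standard
formats (FASTA, 12-column tabular hit files, SAM, TSV).

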
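# Methods

This note records the models, defaults and design choices behind
`estsurvey`, and what the simulator-based validation does and does not
demonstrate about real 454 EST data.

## Read clean-up

Screening tools mark primer/vector contamination by X-masking or
lower-casing. `read_prep.clip_masked` keeps the **longest contiguous
unmasked segment** of each read (leftmost on ties) and discards the read
if that segment is shorter than `min_length` (default 50 nt). Splitting
a read at an internal masked block into two usable fragments would
double-count one cDNA molecule in expression profiles, so the
longest-segment rule was chosen. `N`/`n` count as masked by default
(`mask_n=False` restores plain IUPAC handling). Quality strings are
sliced with the sequence, never re-scored. The operation is idempotent.

## Gene tagging

Hits come from 12-column tabular homology-search output. A query is
assigned the subject of its best hit (maximal bit score) among hits with
e-value ≤ 1e-4; ties break by lower e-value, then lexicographically
smallest subject id, making output order-independent. Subject ids of the
form `GENE.n` are collapsed to `GENE` by default because detection is
counted per locus, not per splice form (`collapse_isoforms=False`
disables this). Subject coordinates are treated as 1-based inclusive at
the interface and orientation-normalized on parse; interval arithmetic
(proteome coverage as per-subject interval unions; 5'/3'
terminal-window overlap with a default 100-residue window) happens on
the normalized intervals.

## Rarefaction and the saturation model

A read pool is the multiset of gene labels of assigned reads. Sampling
is **without replacement** (the pool is a finite, already-sequenced read
set), implemented as multivariate-hypergeometric draws; the default grid
is 20 geometrically spaced sample sizes ending at the full pool, with 10
replicates per size and per-threshold seeded substreams. The exact
expectation

    E[detections](n, k) = Σ_g P(X_g ≥ k),   X_g ~ Hypergeom(N, c_g, n)

is exposed both as a test oracle for the sampler and as a fast
noise-free curve for downstream fitting.

Detection curves are fitted to `y = a·x/(b+x)` by Levenberg–Marquardt
least squares (relative tolerance 1e-8, capped iterations).
Initialization is data-driven: `a₀ = 1.2·max(y)`, `b₀` the linearly
interpolated x at which y first crosses a₀/2 — robust for hyperbolic
data whose asymptote lies above the observed range. Replicate means are
fitted by default (replicate points optionally). R² is `1 − SSE/SST`
with SST about the mean of y. The final slope is evaluated at the
library's total assigned read count (`final_x`), the convention that
reproduces the published per-library slope column exactly. Fits that do
not converge are flagged, not raised. Standard errors come from the
curvature of the least-squares solution; they are indicative only (the
replicate-mean points are heteroscedastic and serially dependent).

## Redundancy classification

`pileup_columns` walks CIGARs of unigene-vs-reference alignments.
Conventions:

* substitutions are keyed by (position, allele) so "identical point
  mutations" group together;
* insertions are anchored to the reference position immediately 5' of
  the inserted bases and keyed by the inserted sequence;
* deletions span their deleted positions — each deleted position
  receives the event, keyed by deletion length — and deleted positions
  count toward depth (the query covers them);
* records whose CIGAR does not consume exactly the stored sequence are
  skipped with a warning and counted.

Classification per covered position: *identical* iff no event at all
(all covering queries carry the reference base — references are
same-species Sanger cDNAs, so agreement with the reference rather than
mere mutual agreement is the meaningful notion; a config toggle is left
for the alternative); *putative variant* iff some substitution allele
has support ≥ 25 or some identical in-frame indel event (length ≡ 0 mod
3) has support ≥ 4; *putative error* iff some substitution allele has
support in [1, 25) or any out-of-frame indel occurs. In-frame indels
below the support threshold belong to **neither** class by default — the
error rule names only out-of-frame indels — with
`inframe_below_threshold_as_error` to fold them into errors. Whether the
in-frame rule requires four *identical* indels or any four is ambiguous
in the underlying description; identical-event grouping is implemented
(the switch above covers the practical difference). Variant and error
flags can co-occur at one position, so the three percentages (per
reference length, 1 dp) may sum to more than 100; report formatting
renders zero counts as `--` and uncovered references as `nd`.

## Library comparison

Expression profiles are compared by Spearman correlation with average
ranks. The default gene universe is the **intersection** (genes detected
in both libraries). The union-with-zeros alternative is available but
not the default: the zero block of dropout genes forms one huge tie
whose internal ordering is pure noise, which deflates the coefficient
far below what paired count tables of real libraries show; published
normalized-vs-raw correlations (~0.70–0.76) are only reproducible on the
both-detected universe. Annotation retention (the chimera proxy) is
plain set arithmetic: |pass ∩ reads-level| / |reads-level|; genes novel
to an assembly pass do not count.

## Enrichment

2×2 table per category `[[k, n−k], [K−k, (N−n)−(K−k)]]`, two-sided
Fisher's exact test by the point-probability method (scipy's
convention: the sum of all tables at fixed margins whose probability
does not exceed the observed one) — verified against brute-force
hypergeometric enumeration. BH FDR is applied across the categories of
one library comparison (one matrix column), matching per-figure
correction practice; the uncorrected variant is a flag. Signed z is
`±Φ⁻¹(1−p/2)` (positive = over-represented), capped at 10 for p = 0.
Hierarchical dotted codes are closed under ancestors before testing, so
a gene in `29.5.1` also counts for `29.5` and `29`.

## The simulator

The simulator generates what the diagnostics assume statistically, with
full ground truth:

* **Transcriptome**: `n_genes` random transcripts (uniform base
  composition, lengths uniform in `length_range`, default 400–2000 nt);
  with probability `p_allelic` (0.3) a second haplotype diverged at
  `allelic_div` (1%) per base; with probability `p_paralog` (0.1) a
  duplicate gene diverged at `paralog_div` (5%), sharing a paralog
  group. The defaults make biological variation present but minor, as
  the single-copy-gene analyses of such surveys indicate (<1% positional
  allelic diversity).
* **Expression**: Zipf-like, weight ∝ rank^(−shape) with shape 1.4
  (log-normal available). Nothing in a survey reports the true
  expression law; the exponent was calibrated once so that, together
  with the default normalization strength, the normalized-vs-raw
  Spearman correlation falls in the published 0.65–0.80 band and the
  non-normalized library shows realistic dropout (roughly half the genes
  untagged at survey-like depth). It is not claimed to match any
  particular tissue.
* **Normalization**: weight exponentiation `w^γ` renormalized, default
  γ = 0.35. Duplex-specific-nuclease kinetics are not modelled; rank
  order is preserved exactly, so all decorrelation between normalized
  and raw profiles comes from sampling — a known simplification.
* **Reads**: i.i.d. by gene weight, haplotype uniform; lengths normal
  with platform defaults (GS20: 100 ± 8 nt, GS FLX: 230 ± 12 nt); start
  positions geometrically biased toward the 3' end with decay
  `three_prime_lambda` (default 0.001 ≈ mild poly-dT bias; 0 = uniform);
  reads longer than their transcript are truncated and flagged.
* **Errors**: substitutions at `sub_rate` = 0.008 per base; at each
  homopolymer run of length r ≥ 2 the run length changes by exactly ±1
  unit with probability `hp_indel_rate·(r−1)` (`hp_indel_rate` = 0.01)
  — together ≈ 1% total error dominated by homopolymers, the 454 error
  profile. Every planted event is recorded in the truth table.
* **Alignment sets** (for the redundancy classifier): near-full-length
  unigenes from a two-haplotype gene, ungapped against haplotype 1,
  variant positions planted ≥ 100 bp from the ends so every
  variant-carrying unigene covers them and allele support crosses the
  25-unigene threshold cleanly.

Seeding: a single master seed; every stage and library derives an
independent substream from (seed, stage tag), so identical configs give
byte-identical FASTA and truth output.

**What passing the simulator-based tests shows — and does not.** It
shows the estimators are correct on data satisfying their assumptions
(i.i.d. sampling, known truth, no assembly step). Real surveys add
chimeric unigenes, flow-value-dependent error rates, quality-dependent
trimming, cross-species annotation transfer and assembler behaviour,
none of which the simulator emulates (quality scores, flowgrams and
chimera simulation are explicitly out of scope). Results on simulated
data therefore validate the arithmetic, not the biology.

## Problem sizes

Validation uses scaled-down but structurally faithful sizes chosen for
fast, deterministic tests: rank-correlation checks on 3,000 genes ×
48,000 reads (the gene-to-read ratio of the real libraries), fit
recovery on 50 noisy curves at survey-like depths (asymptote ~13,000
genes, final depth 270,000 reads), classifier recovery on 60 unigenes ×
600 bp over 20 seeds, and enrichment null calibration on 1,000 Fisher
tests over a 10,000-gene background. The published per-library slope
column is recomputed exactly from the printed (a, b) and final read
counts.

## Known limitations

* The pipeline's orchestrated run tags reads from simulator ground
  truth; real hit files go through `gene_tagging` explicitly (running
  the homology search itself is out of scope).
* Confidence intervals for (a, b) are curvature-based only; no
  bootstrap by default.
* The classifier does not phase variants into haplotypes and cannot
  separate allelic from paralogous variation — by design, as the
  underlying study could not either.
* topGO-style graph-decorrelated GO testing is not implemented; flat
  Fisher tests on propagated hierarchies are.
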
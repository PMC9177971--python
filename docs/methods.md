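# Methods

## The measurement model

Three assays probe successive stages of expression at every locus *g*:

* **Pol II ChIP-seq** measures where elongating (S2P) polymerase sits on
  the DNA. Its signal is occupancy plus a uniform background that the
  **input** library (sheared chromatin, no immunoprecipitation) measures
  alone.
* **Pol II RIP-seq** sequences the RNA attached to that polymerase —
  nascent transcripts, partially unspliced.
* **pA RNA-seq** measures spliced, polyadenylated steady-state RNA.

With θ the replicate-averaged TPM of a locus per assay, the pipeline
computes transcription efficiency `TE = θ_RIP/θ_ChIP`, RNA stability
`S = θ_pARNA/θ_RIP`, occupancy change `Δ = log2(θ_ChIP^mut/θ_ChIP^wt)`, and
RNA output `θ_ChIP·TE·S`, which telescopes to `θ_pARNA` identically — the
decomposition re-expresses steady-state RNA as a product of three
interpretable factors rather than adding information.

Silencing contributions are quantified against *clr4Δ*, taken as the
zero-heterochromatin reference: per region and pathway,
`FC_p = measure_p(clr4Δ)/measure_p(wt)`. Since output is multiplicative
only log fold changes are additive, so shares are computed in log2 space,
`share_p = log2 FC_p / Σ_q log2 FC_q`. The share formula is a modeling
choice of this package: it is the unique convention under which shares of a
multiplicative identity are additive and sum to exactly 1 whenever all
`FC_p > 1`; a pathway that opposes silencing (`FC_p < 1`) receives a
negative share and is flagged rather than clipped, because compensation
(e.g. efficiency restored but degradation increased) is a real phenotype.
Residual contributions per mutant are `log2(measure_p(clr4Δ)/measure_p(mu))`
— zero when the mutant has fully lost the pathway.

Regions aggregate member genes by **summing θ before any ratio is taken**
(ratios of sums, never means of per-gene ratios); sums are robust to
members with few reads, and the region fold change inherits exactness when
member-level fold changes are uniform. Strand-resolved reporting
(`by_strand`) splits a category by member strand before summing.

## Counting rules

Single-end reads are assigned by intersection-strict semantics evaluated
over the **gene span** (exons + introns): a read counts for a gene iff every
base lies within the span and no second gene also contains the whole read.
Span-level (rather than exon-level) evaluation is deliberate: ChIP reads
and intron-retaining nascent reads must still count toward their gene.
For RNA assays the read strand must equal the gene strand; ChIP/input are
unstranded. Reads touching an rRNA gene at any mapped location are removed
before anything else.

Multi-mapping reads (NH > 1) are counted only when NH < 16 and every mapped
location lies inside a heterochromatic gene of one shared repeat family;
the read then adds exactly 1 to the family's **representative copy**. The
cut-off removes low-complexity reads while keeping reads from the 12–13
copy dg/dh families; the "every location" requirement is the strict reading
of heterochromatic eligibility, and a relaxed mode (`require_all_het=False`)
that ignores non-heterochromatic locations is available behind a flag.
When no representative is flagged in the input the lowest-coordinate member
is chosen, deterministically. Counts are integers; fractional 1/NH weights
exist only in coverage profiles.

TPM uses the gene span length and is computed over all counted genes
(everything but rRNA): `TPM_g = 10⁶ (c_g/L_g)/Σ_h(c_h/L_h)`. Replicates
are averaged after a concordance filter: pairwise Spearman of
`log2(TPM+1)` over genes expressed in at least one replicate must reach
0.8; the worst-correlated replicate is removed iteratively, and a
condition whose last two replicates disagree is an error carrying the full
correlation matrix. The `log2(TPM+1)` transform and the expressed-gene
restriction are package choices (a log transform needs a pseudocount, and
all-zero genes carry no rank information).

Intron retention — the QC that distinguishes nascent from mature RNA — is
`(intron reads / intron length) / (gene reads / gene length)` per intron,
NA for unexpressed genes.

## Input subtraction

The three central-core regions (Cenp-A chromatin) are long and
transcriptionally near-silent, so IP coverage there is pure background.
For each region `λ_r = Σx_i / Σy_i` solves `Σx_i − λΣy_i = 0` on the raw
coverage profiles (x = IP, y = input); the final λ is the median of the
three, making the estimate robust to one anomalous region. The released
track is `max(x − λy, 0)`; the signed region sums are kept as QC (the
median region's is zero by construction).

Gene-level ChIP signal, however, is computed from the **signed** difference
averaged over the gene and clamped at zero per gene, not per base:
per-base clamping rectifies noise and inflates genes whose signal is small
against the background, biasing between-genotype fold changes (observable
in this package as a compressed ΔPol II at weakly occupied repeats).
Repeat families report the member-summed mean depth at the representative
copy, keeping θ_ChIP commensurate with the representative-copy counting of
θ_RIP/θ_pA; the per-gene values are rescaled to sum to 10⁶ so θ_ChIP lives
on the same TPM-like scale as the count-based θs. Each ChIP replicate is
paired with the input replicate of the same genotype and index.

## The synthetic-data generator

Per gene the truth is occupancy `o ≥ 0`, efficiency `e ∈ (0,1]`, stability
`s > 0`; expected signal is `o·span` (ChIP, plus uniform background),
`o·e·span` (RIP), `o·e·s·exonic` (pA), background only (input). Reads are
Poisson around depth-scaled expectations (optional gamma overdispersion),
placed uniformly — within single exons for the spliced fraction, across the
span for the intron-retaining fraction (`rho_nascent = 0.3` for RIP,
`rho_mature = 0.02` for pA). RNA reads carry the transcript strand. A read
from a repeat family is emitted once per copy at the same offset with
NH = family size — exactly the alignment records a real multi-mapper
produces.

The toy genome (one ~396 kb chromosome) contains ~200 protein-coding genes
(1 kb; every 7th with a 150 bp intron), a 12-copy dg family, a 13-copy dh
family, 2 tlh repeat genes, 6 other subtelomeric genes, cenH and mat, three
20 kb silent central-core regions and 2 rRNA genes. The dh family is
modeled as strand-homogeneous subfamilies (7 forward, 6 reverse) so that
multi-mapper strand semantics are well defined and strand-resolved dh
reporting is exercised; dh transcripts from the two strands are given
1.5-fold different stability. The central cores are deliberately the
longest features — λ's precision is set by the background reads they
collect.

Default study conditions: depth 10⁵ reads per assay, two replicates, read
length 50, ChIP background fraction 0.3 (input is pure background, RNA
assays background-free). Wild-type parameters: euchromatic `o` log-normal
(σ = 0.5, shared across genotypes at a given seed), `e = 0.5`, `s = 1`;
heterochromatic loci have `e` 8-fold lower; repeats have `o = 0.1` and
reduced `s`. The *clr4Δ* scenario multiplies repeat (o, e, s) by
(2^2.0, 2^1.44, 2^2.1) — silencing shares 36.1/26.0/37.9 % — and restores
subtelomeric/mat loci toward euchromatic values; at tlh the factors are
(2^2.0, 2^5.08, 2^0.615) (shares 26/66/8 %, efficiency-dominated, with
`e_wt(tlh) = 0.015`). Note that *clr4Δ* does not restore repeat efficiency
fully to euchromatic levels: only the Clr4-dependent part of the efficiency
deficit (2^1.44 of the 8-fold) is released, which is what makes the three
shares sum as they do. Ccr4–Not mutants (caf1/ccr4/mot2) restore
efficiency to that heterochromatin-independent level while occupancy stays
wild-type-like and degradation increases; chromatin mutants (swi6/clr3)
partially release occupancy instead. These per-category profiles are what
the mutant-panel embedding separates.

What the generator does **not** emulate: sequence content (no error or
mappability model), fragment-size or GC effects, paired ends, biological
replicate variance beyond Poisson (unless overdispersion is switched on),
background reads that themselves multi-map (background is emitted NH = 1
everywhere, harmless because λ-subtraction cancels the same convention on
both sides), and partial sequence divergence between repeat copies. Tests
passing on these simulations therefore validate the *arithmetic and
bookkeeping* of the pipeline — counting rules, normalization, subtraction,
decomposition algebra, parameter recovery under sampling noise — not
robustness to alignment artifacts in real libraries.

## Numerical choices

* θ values below 1 TPM yield NA ratios instead of unstable quotients.
* Spearman threshold comparisons carry a 1e-12 epsilon so a coefficient of
  exactly 0.8 passes "at least 0.8".
* The median of three λ values is the middle order statistic (no
  averaging); ties resolve to the repeated value.
* TPM of an all-zero sample is NA with a warning; a zero-input core region
  is an error naming the region.
* SEM of a ratio of unpaired replicate sets: all n×m pairwise ratios,
  `sd(ratios, ddof=1)/√(nm)`; zero denominators excluded with a warning.
* t-SNE: scikit-learn, perplexity 5, seeded; perplexity is capped below the
  row count with a warning on small panels. Cluster statements are asserted
  in feature space (Euclidean), not on embedded coordinates — t-SNE
  geometry is not a stable test target.
* The TE component of the feature vector is scaled by 100 before
  `log2(·+1)` to put a ratio of order 1 on a TPM-like magnitude
  (configurable).

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
the study-scale dataset is 2 genotypes × 4 assays × 2 replicates at 10⁵
reads per assay on the toy genome; oracle-equivalence checks use 200 random
instances of ≤ 500 reads × ≤ 30 genes; the sampler's law-of-large-numbers
check uses 200 replicates at reduced depth on a 15-gene genome. At these
sizes the pericentromeric estimates are tight (a few percent), while the
2-copy tlh family draws only a handful of pA reads, so its stability share
fluctuates visibly between seeds — a faithful depiction of how the real
quantities behave at low coverage.

## Limitations

Paired-end logic, UMI/deduplication, alignment itself and batch effects
are out of scope; the pipeline consumes alignments. Whether the original
analysis applied input subtraction at per-base or per-gene level before
TPM, which dg/dh copy served as representative, and the exact feature
scaling used before embedding are not derivable from the source material;
each is exposed as a documented, configurable choice with the defaults
described above.
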
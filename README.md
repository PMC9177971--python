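# hetsilence

Quantitative decomposition of heterochromatic silencing in fission yeast
from three sequencing assays: S2P-Pol II **ChIP-seq** (with input control),
S2P-Pol II **RIP-seq** of nascent RNA, and **poly(A) RNA-seq** of
steady-state RNA.

Heterochromatic loci (pericentromeric *dg*/*dh* repeats, subtelomeric
*tlh*, the *mat* locus) can be silenced by keeping RNA Pol II off the DNA,
by making bound Pol II unproductive, or by degrading the RNA after it is
made. With θ the replicate-averaged TPM of a locus in each assay, the three
pathways are

```
transcription efficiency   TE = θ_RIP / θ_ChIP
RNA stability              S  = θ_pARNA / θ_RIP
ΔPol II occupancy              = log2(θ_ChIP^mut / θ_ChIP^wt)

RNA output = θ_ChIP · TE · S   (= θ_pARNA identically)
```

Because RNA output is multiplicative, the contribution of pathway *p* to
silencing is measured in log space relative to a strain with no
heterochromatin at all (*clr4Δ*, lacking the H3K9 methyltransferase):
`share_p = log2 FC_p / Σ_q log2 FC_q` with `FC_p = measure_p(clr4Δ) /
measure_p(wt)` evaluated on region-aggregated θ.

The package implements the complete analysis stack around these ratios:

* **genome model** — gene models with heterochromatin categories, repeat
  copy-groups (one representative copy per family), the three silent
  central-core background regions; GFF3/BED6 I/O.
* **counting** — intersection-strict assignment of single-end reads over
  gene spans; strand matching for RNA assays; rRNA removal; multi-mappers
  counted once at the representative repeat copy when NH < 16 and all
  locations fall in one heterochromatic copy family; TPM; Spearman ≥ 0.8
  replicate QC; intron-retention ratios (nascent-RNA quality control).
* **coverage** — per-base profiles with fractional 1/NH multi-mapper
  weights; wiggle/bedGraph tracks; input subtraction anchored on the scaling
  factor λ that zeroes the median silent central-core region.
* **metrics** — TE, stability, ΔPol II, RNA output, region aggregation
  (ratios of summed θ, optionally strand-resolved), pathway shares,
  residual contributions per mutant, pairwise-replicate SEM of ratios.
* **simulate** — a generative model of all four assays on a toy genome
  (Poisson reads around closed-form expectations, multi-copy repeat
  families emitted as true multi-mappers, stranded RNA reads, uniform
  background captured by input), so every stage is testable offline.
* **pipeline** — sample-sheet-driven orchestration with a hashed manifest,
  mutant feature matrices and a seeded t-SNE embedding (perplexity 5).

## Worked example

`examples/04_silencing_decomposition.py` simulates wild type and *clr4Δ*
(4 assays × 2 replicates × 100 000 reads), runs the full pipeline and
prints, among other rows:

```
pathway decomposition (clr4 relative to wild type):
                     fc_occupancy  fc_efficiency  fc_stability  fc_output
region
centromeric_repeats          3.85           2.73          3.33      35.03
tlh                          4.20          16.93          2.91     206.78

contribution shares (% of total log2 RNA-output change):
                     share_occupancy  share_efficiency  share_stability
region
centromeric_repeats             37.9              28.3             33.8
tlh                             26.9              53.1             20.0
```

Reading the first row: losing heterochromatin raised Pol II occupancy at
the centromeric repeats ~4-fold, transcription efficiency ~2.7-fold and RNA
stability ~3.3-fold, so in wild type the three pathways contributed roughly
38/28/34 % of repeat silencing — RNA degradation and transcriptional
silencing (occupancy + efficiency) of comparable importance. At the
subtelomeric *tlh* repeats silencing is predominantly transcriptional, with
reduced efficiency the major pathway. The generative truth behind this
simulation is 36.1/26.0/37.9 % at the repeats and 26/66/8 % at *tlh*; the
repeat estimates sit within a few points of truth at this depth, while the
*tlh* stability share is read-limited (the *tlh* family draws only a
handful of pA reads at 10⁵ reads/assay, so its split fluctuates more).
Other examples demonstrate the counting rules, λ subtraction and the
mutant-panel embedding.

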
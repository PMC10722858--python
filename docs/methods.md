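# Methods

This note documents the statistical models, the synthetic-data generator,
and the design choices made where the design was genuinely open. Everything
stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Mixed-model association

The per-marker model is `y = Qα + xβ + u + e` with `u ~ N(0, σ²g K)` and
`e ~ N(0, σ²e I)`.

* **Kinship.** Centered genomic relationship `K = WWᵀ/c`,
  `c = Σⱼ 2pⱼ(1−pⱼ)`, `W` the column-centered, per-SNP mean-imputed dosage
  matrix. Missing genotypes are preserved in storage and imputed only in
  design matrices, which keeps the missing-call-frequency filter meaningful.
* **Structure.** Top-k genotype principal components (default k = 3) of the
  centered, unit-scaled dosage matrix stand in for model-based ancestry
  fractions; the two corrections are interchangeable for this purpose and
  PCs keep the pipeline self-contained. Sign is fixed per component (largest
  |loading| positive) so results are bit-reproducible.
* **REML.** The null model (no marker) is fit by profiling `σ²g` out of the
  restricted likelihood on the spectrum of `K`, searching
  `log δ ∈ [−11.5, 11.5]` (`δ = σ²e/σ²g`, i.e. log10 δ ∈ [−5, 5]) on a
  100-point grid with bounded local refinement (xatol 1e−10). At a boundary
  the corresponding component is reported as 0. A constant trait returns an
  explicit degenerate fit. With `K = I` the profile is flat in δ; the sum
  `σ²g + σ²e` then equals the OLS residual variance (tested).
* **Scan (P3D).** Null-model components are reused for every marker: rotate
  by the eigenvectors of `K`, whiten by `√(λᵢ + δ)`, project out `[1, Q]`,
  and run one vectorized OLS pass over all markers. The Wald t-statistic
  uses the per-model residual variance with `n − p − 1` degrees of freedom,
  so at `K = I` with no covariates the P-values are exactly the 1-df F-test
  (acceptance-tested to 1e−6 relative). Compression of individuals into
  groups is deliberately omitted: it is a speed optimization that converges
  to this uncompressed model, and desk-scale data do not need it.
* **Variance explained** is the squared partial correlation of the marker
  given the covariates on the decorrelated scale, equivalently the
  proportional reduction in residual sum of squares when the marker enters —
  verified against a brute-force two-model refit.
* **Collinear markers** (zero residual variance after projection) get
  β = 0, P = 1 and a flag.
* **Trait transform.** mGWAS runs on `log2(replicate mean + 1)` by default
  (configurable to raw): metabolite intensities are heavy-tailed (typical
  CV > 50%) and the log stabilizes them.
* **Thresholds.** MAF > 0.05 and MCF < 0.1 are strict inequalities;
  the significance rule `P ≤ threshold` is inclusive; the default per-test
  threshold is 0.05/m with m the tested SNPs, and a fixed externally chosen
  constant can be passed instead. Lead-SNP ties break to the smaller
  position.

## Heritability

Replicate one-way ANOVA per metabolite: `var(E) = MS_within`,
`var(G) = max(0, (MS_between − MS_within)/r)`,
`H² = var(G)/(var(G)+var(E))` (0 when both components vanish; error with
r = 1). The estimator is affine-invariant, so the scale on which it is
applied matters only through distribution shape; pipelines apply it to the
log2-scale values, the scale on which the generator's variance components
are defined — on raw exponentiated intensities the estimate is biased low
by the nonlinearity (measured ≈ −0.04 at H² = 0.8).

## Signals

* **Clumping.** Within a chromosome, maximal runs of significant SNPs with
  every consecutive gap < gap_bp (default 1 Mb); runs of ≥ min_snps
  (default 5) become loci, smaller runs go to a remainder list; lead = min P.
  Verified exactly against an exhaustive reference on 1000 random instances,
  and idempotent.
* **Hotspots.** Equal-width bins per chromosome (default 1 Mb; the last
  partial bin is kept and treated as full-width — the bias is negligible at
  these scales). Null: each of 1000 permutations throws all S signals
  independently uniformly over the B bins; per-bin counts are pooled over
  bins × permutations; threshold = smallest c with null `Pr(count ≥ c) <
  0.01`. At S = B = 1000 the permutation threshold matches the analytic
  Binomial(S, 1/B) upper quantile within 1. The counted "signal" is one
  lead-SNP association per locus per trait (locus-level counting avoids
  LD-driven double-counting); counting all significant SNP pairs instead is
  a caller choice.
* **Co-localization.** A metabolite locus pairs with a phenotype locus when
  the lead SNPs are on the same chromosome within window_bp (default 1 Mb,
  matching the clump gap) or the locus intervals intersect. There is no
  canonical definition of "co-located" at this granularity; the window rule
  plus interval intersection covers both common readings and each pair is
  annotated with which rule fired and the lead distance.
* **Replicate intersection** matches lead SNPs across two replicate locus
  lists by trait, chromosome, and |Δpos| ≤ match_bp (default 0 = exact),
  greedily by position with each locus used once.

## Domestication analytics

* **PLS-DA VIP.** PLS1 by NIPALS on column-centered, unit-scaled data
  against the centered 0/1 class indicator;
  `VIP_j = √(p·Σ_a SSY_a w²_aj / Σ_a SSY_a)` with unit-norm weights and
  `SSY_a = q²_a t_aᵀt_a`. `ΣVIP² = p` is enforced by construction and
  asserted to 1e−8 on every fit; scores agree with evaluating the same
  formula on weights fitted by an independent NIPALS implementation to
  machine precision. Components default to A = 2 (recomputed per resample on
  the small subtable; A caps at the model rank). Plain PLS-DA is used, not
  the orthogonalized variant.
* **Fold-change** is cultivated/wild on the raw scale (the direction is
  always reported, so the opposite orientation is recoverable); VIP is
  computed on log2 intensities. |FC| ≥ 1.5 is inclusive at the boundary; a
  zero wild mean yields +∞, flagged upward.
* **DAM rule.** 10 repeats, each drawing 5 cultivated accessions without
  replacement (fresh seeded draw per repeat) against all wild accessions;
  per-repeat flag = VIP ≥ 1 AND FC outside [1/1.5, 1.5]; DAM ⇔ flagged in
  all 10 repeats **with the same direction**. Direction consistency is an
  interpretation choice: mixed-direction flags would be biologically
  incoherent.
* **Nucleotide diversity.** Per biallelic site with n non-missing allele
  calls and alt count c, diversity `2c(n−c)/(n(n−1))` (symmetric in allele
  labels); window π sums sites in half-open [start, start+window) and
  divides by window_bp — every position assumed callable, no accessibility
  mask — reported 1-based inclusive, sliding by step_bp (defaults 80 kb /
  10 kb). Diversity is computed on **unfiltered** genotypes: the MAF filter
  would strip exactly the near-fixed sites a sweep produces.

## Metabolome descriptives

Replicate reproducibility: Pearson r between replicates across accessions,
pass ⇔ r > 0.25 and P < 0.01 (strict; undefined below 3 complete pairs).
CV is SD/mean of raw replicate means in percent. Metabolite correlation uses
Pearson on log2(replicate mean + 1) (means are taken before the log:
transformed replicate means), average-linkage on 1 − r, leaf order made
deterministic by sorting metabolite ids first. Accession clustering emits a
neighbor-joining tree for display and takes the k-group partition from
average linkage on the same Euclidean log2 distance matrix, because an
unrooted NJ tree carries no canonical k-cut; k is a parameter with no
automatic selection. Group-vs-trait contrasts use all pairwise Welch t-tests
with Benjamini–Hochberg adjustment and a greedy compact-letter display;
this replaces classical multiple-range testing, whose critical-value tables
are nonstandard, while preserving the letters-on-boxplots semantics.

## Candidate genes

Gene windows are `[start − flank, end + flank]` with inclusive bounds and a
strand-symmetric 2-kb default flank. Window association reuses the
genome-wide null fit; "possible causative" defaults to Bonferroni over the
window's SNPs (configurable to the genome-wide threshold). Expression is
consumed as a precomputed table, never computed. Allele contrasts default to
carrier (calls ≥ 1) vs non-carrier two-group Welch tests — matching
two-group allele boxplots — with a genotypic 3-class option; joint
2–4-SNP combinations group by the carrier string with a minimum group size.

## The synthetic-data generator

The generator's defaults are the study conditions: 299 cultivated + 5 wild
accessions, 2 biological replicates, per-metabolite H² = 0.6, planted QTLs
at 20–30% of trait variance, domestication |log2FC| = 2–2.5, and a
400-kb swept window — on a deliberately small genome (2 chromosomes × 5 Mb,
6000 SNPs) chosen so the full chain runs in seconds while every downstream
stage still has the structure it needs (LD runs for clumping, two diverged
populations for structure correction, replicate noise for H²).

* **Genotypes.** Ancestral frequencies Beta(0.5, 0.5) clipped to
  [0.05, 0.95]; cultivated/wild frequencies from the Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) divergence model (F = 0.3 default, the
  strong crop/wild contrast of a domestication bottleneck). LD is a
  first-order Markov copying process on each haplotype: with probability
  ld_rho (0.9 default) the allele state carries forward from the previous
  SNP on the chromosome, else it is drawn fresh at that SNP's group
  frequency. This yields genotype correlation ≈ ρ^k between SNPs k apart
  (measured to match) — the run structure locus clumping assumes. Realized
  per-SNP frequencies are consequently an exponential moving average of the
  drawn frequencies; the Fst contrast survives. Copying a latent uniform
  rank instead (an alternative first-order scheme) decorrelates thresholded
  alleles when neighboring frequencies differ and produces no usable LD
  runs, which is why state copying was chosen.
* **Sweep.** Each cultivated haplotype adopts the window's major allele at
  99% of sweep-window sites, emulating the near-fixation of one swept
  haplotype; realized cultivated frequencies end near 0.99/0.01 and the
  cultivated/wild π ratio inside the window is ≈ 0.02 (≈ 1 outside).
  Frequency-level pushing interacts badly with Markov LD (alternating
  0.99/0.01 targets average back to 0.5), hence the haplotype-level design.
  No explicit selection dynamics are modelled; only the diversity contrast
  matters downstream.
* **Metabolome.** Per metabolite on the log2 scale: genetic value =
  Σ_q √(f_q·varP)·z_q + polygenic N(0, σ²K), where z_q is the standardized
  QTL dosage and f_q the configured fraction of replicate-mean trait
  variance. The polygenic draw is orthogonalized in-sample against the QTL
  genotypes and every component is empirically standardized, so the realized
  variance shares equal the configured ones in each dataset (without this,
  random QTL–polygenic covariance moves realized shares by tens of percent
  between realizations). Genetic variance is scaled to H², each replicate
  adds N(0, 1−H²), DAM metabolites add their log2FC to the cultivated mean,
  and raw intensities are 2^(10 + value), hence strictly positive. H² = 1
  with replicates requested is rejected (the ANOVA estimator would be
  degenerate).
* **Phenotypes.** SR weight = intercept + Σ coef × log2 metabolite mean +
  Gaussian noise; the binary color trait thresholds a liability proportional
  to a designated anthocyanin-like metabolite's centered log2 level.
* **Determinism.** One master seed; fixed per-component offsets (+1
  genotypes, +2 metabolome, +3 phenotypes). Identical config + seed gives
  byte-identical VCF output (tested).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genotyping error and call-rate structure beyond
random missingness; coalescent LD (the Markov chain has geometric, not
recombination-map, block lengths); allele-frequency spectra shaped by
demography (the EMA smooths the Beta spectrum); metabolite annotation,
batch effects, and detection-limit censoring; shared pathway structure
beyond pairwise correlation induced by shared kinship; and multi-trait
pleiotropy except where planted.

## Problem sizes

The test suite and acceptance script use: 50×500 panels for the OLS
equivalence; n = 300 with ~20,000 markers for type-I calibration; 50
simulations of n = 300, m = 5000, ρ = 0.9 for QTL recovery; 100 metabolites
per H² level; 1000 random clumping instances; 50 hotspot seeds at S = 300,
B = 200 plus one S = B = 1000 oracle comparison; 20 seeded DAM runs. These
sizes give Monte-Carlo error comfortably inside each check's tolerance while
the whole suite runs in well under a minute of compute for the statistical
parts.

## Known limitations

* The MLM is single-marker with P3D; no exact per-marker REML, multi-locus,
  Bayesian, or dominance models.
* No LD-based (r²) clumping or fine-mapping; clumping is purely positional.
* The hotspot null treats partial end-of-chromosome bins as full-width.
* PCs are a linear structure correction; admixture with more than a few
  latent populations may need larger k.
* The compact-letter display is greedy (insertion order), not a minimal
  letter assignment; letters are a readable summary, not a test statistic.
* Windowed π assumes all positions callable; with real accessibility masks
  the per-bp denominators would differ.
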
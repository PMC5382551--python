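# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices, and the limits of what the test suite demonstrates.

## Two-color array model and differential expression

### Background correction (normexp)

Observed spot intensity is modeled as X = B + S, B ~ N(μ, σ²) independent
of S ~ Exp(mean α). The corrected intensity is the posterior mean

    E[S | X = x] = μ_s + σ·φ(μ_s/σ)/Φ(μ_s/σ),   μ_s = x − μ − σ²/α,

which is strictly positive and strictly increasing in x, so log-ratios are
always defined after correction. Numerics: the inverse Mills ratio is
evaluated as √(2/π)/erfcx(−z/√2); erfcx is stable for arbitrarily negative
z, so no asymptotic-series branch or clipping is needed (a floor at the
smallest positive float guards the x → −∞ limit). Parameters are estimated
per array and channel by maximum likelihood on the Normal+Exponential
convolution density, started from method-of-moments values (the exponential
component carries the skewness: m₃ = 2α³) and refined by Nelder–Mead on
(μ, log σ, log α). Estimation operates on observed foreground intensities,
which follow the generative model directly; the scanner's measured local
background is carried in the data model but not pre-subtracted, which would
create negative inputs and double-count the background mean.

### Normalization

1. Optional control-RNA step: the mean M of designated control probes is
   subtracted per array (the role a small control RNA plays on the real
   platform), before any model-based normalization. On by default,
   switchable off.
2. Within-array: robust cubic B-spline of M on A. Defaults: 5 basis
   functions (df), interior knots at equally spaced A-quantiles, Huber
   weights with c = 1.345 on the MAD scale, 10 reweighting iterations.
   Fewer than 5·df probes triggers a fallback to median-centering with a
   logged warning — a spline on so few points would chase noise.
3. Between-array: each array's M is divided by its median absolute
   deviation and rescaled to the geometric mean of the per-array MADs, the
   standard "scaling" interpretation for log-ratios. A zero-MAD array is an
   error naming the array, not a silent skip.

### Moderated t

Per-probe OLS gives (β̂_g, s²_g, d_g). Under the hierarchical model
s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g with scaled inverse-chi-square prior
σ²_g = d₀s₀²/χ²_{d₀}, the marginal of s²_g is s₀²·F(d_g, d₀) and

    E[log s²] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[log s²] = ψ′(d/2) + ψ′(d₀/2).

Matching empirical mean/variance of log s² and inverting the trigamma
(Newton, 50 iterations, tolerance 1e-10·x) yields (d₀, s₀²). Posterior
variances s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) shrink monotonically toward
s₀²; the moderated t uses d₀ + d_g df (normal tail when d₀ = ∞). Edge
cases: a non-positive variance of the digamma-corrected residuals means no
excess dispersion → d₀ = ∞ (full pooling); exactly zero dispersion of
log s² (all s² equal) reports s₀² equal to that common value, the only
self-consistent answer when the data show no sampling scatter at all;
`d0_override=0` disables pooling and reproduces the ordinary t exactly,
which the tests assert.

p-values are two-sided. The 10⁻⁴ significance cut-off is applied to
*adjusted* p by default (Bonferroni), configurable to raw p or BH; the
top-N ranking (default 100) sorts by adjusted p with ties broken by |β̂|
descending then probe id, so it is total and deterministic. Whether a
ranking of this design should use adjusted p, raw p, or fold change is
genuinely open; the choice here is documented, not claimed canonical.

## qPCR quantification and nonparametric tests

ΔCp = Cp_gene − Cp_reference per sample; one expression doubling lowers Cp
by one cycle, so higher dCp means lower expression — every correlation on
dCp states this reversed-scale convention. ΔΔCt uses the arithmetic mean of
group dCp (the standard definition; configurable), fold change = 2^(−ΔΔCt),
emitted on both linear and log₂ scales since conventions differ between
labs. Missing Cp values propagate as missing and are excluded pairwise,
never imputed; a below-detection-limit measurement maps to missing with
reason code `below_detection` in concordance output.

Mann–Whitney U: for n+m ≤ 12 the p-value enumerates all C(n+m, n)
assignments of the pooled mid-ranks (exact under ties; at the cut-off that
is 924 assignments, microseconds of work); larger samples use the normal
approximation with tie and continuity correction. The exact two-sided p
counts assignments with |U − nm/2| ≥ |U_obs − nm/2|, which gives the
closed-form 2/C(10,5) for complete separation at n = m = 5 and p = 1 for
identical multisets. Spearman's ρ is Pearson on mid-ranks; p is exact by
permutation for n ≤ 8 (≤ 40 320 permutations) and a t-approximation above.
Cross-platform concordance inner-joins two per-gene value maps, records the
excluded ids with reasons, and reports Spearman on the matched set
(undefined below 3 matches).

## Target consensus

Seed-site taxonomy is the canonical one: 6mer = reverse complement of
miRNA positions 2–7 on the UTR sense strand; 7mer-m8 extends pairing to
position 8; 7mer-A1 adds an adenine opposite position 1; 8mer has both.
Each 6mer-core locus is reported once with the strongest type it supports —
so site counts are counts of loci, not of overlapping type variants. N
never matches. Coordinates are 0-based half-open everywhere, including BED
output and error messages.

Consensus is defined at the gene–miRNA pair level: a pair is retained iff
≥ k of n predictors report at least one site for it (strict full consensus
is k = n; a relaxed mode restricts to a named predictor subset, e.g. two
specific algorithms). A gene-level variant (k predictors anywhere on the
gene) is available by flag. Sites of retained pairs are merged per miRNA by
interval union (overlap ≥ 1 nt), with supporting predictors unioned; merging
is idempotent and order-invariant, verified against a pairwise-fixpoint
oracle. Prioritization thresholds the TOTAL merged site count per gene
(default ≥ 4), counting multiple sites of the same miRNA — the alternative
reading, distinct supporting miRNAs, is one flag away. Whether binding
sites should be deduplicated across algorithms before counting is not
something upstream tools agree on; the union-merge rule here is an explicit
design decision. Biology-specific exclusions (e.g. dropping a gene because
it is itself part of the miRNA machinery) are a user-supplied exclusion
list, never hard-coded.

## CRE scanning

Exact string matching of the palindromic octamer TGACGTCA, no
position-weight matrix — the consensus string is exact, whereas matrix
libraries and similarity thresholds vary by vendor and vintage and are not
recoverable. Because the motif is its own reverse complement, a
single-strand scan is strand-complete; this property is checked at runtime
for whatever motif is supplied and logged (non-palindromic motifs scan the
given strand only, with a warning). Overlapping occurrences are all
reported. Expected hit count on iid uniform sequence is (L−7)·4⁻⁸ ≈ 15.3
per Mb, which the scanner reproduces within Poisson error.

## Synthetic-data generators

All generators derive independent named RNG streams from one integer seed
(CRC32 of a stream label mixed into a `SeedSequence`), so runs are
bit-reproducible and adding a stream never shifts the others.

* **Two-color arrays** follow the normexp generative model exactly:
  truncated-Gaussian background (μ = 100, σ = 15) plus exponential signal
  (mean 200) per spot. The signal is drawn once per spot and split across
  the two dyes by the true ratio, as on a physical array where both
  channels read the same feature; differential probes shift the dye ratio
  symmetrically (±effect/2 per channel) on treated arrays so M stays
  centered for normalization tests. Defaults: 580 probes, 2 × 5 arrays, 6%
  truly differential (35 probes) at |log₂FC| = 2, four null control probes.
  Not modeled: spatial artifacts, dye swaps, cross-hybridization — so
  passing tests say nothing about those real-data failure modes.
* **Cp tables**: base Cp uniform in [20, 30] per gene, treated samples
  shifted by −log₂FC, Gaussian cycle noise (default sd 0.25, n = 5 per
  group as in a typical small animal cohort). The reference gene must be
  present with true fold change 0. Noise-free tables invert exactly under
  ΔΔCt — the generative/analytic duality the tests assert.
* **UTR sets**: requested sites (default the strongest, 8mer) are placed
  non-overlapping with ≥ 2 nt spacers via order statistics of uniform
  draws; the background is then *repaired* — scanned for accidental seed
  matches of any listed miRNA and mutated one background base per offending
  window until clean. This reaches the same postcondition as rejection
  sampling (the planted truth is exactly the detected site set, verified
  in tests by an independent naive scan) but with non-vanishing acceptance
  probability at kilobase lengths, where whole-sequence rejection against
  ten 6mer seeds would essentially never accept. Real UTRs, of course,
  are not match-scrubbed uniform sequence; planted-recovery results
  quantify bookkeeping correctness, not biological sensitivity.
* **Pseudo-predictors**: each profile keeps a truth site with probability
  `sensitivity`, jitters reported boundaries by ≤ 3 nt, and adds Poisson
  false calls at `false_calls_per_kb`. Perfect profiles reproduce truth
  exactly, giving the perfect-predictor identity test for k = n consensus;
  at sensitivity s, pair-level recall under k-of-n is s^k, which the tests
  check against the binomial closed form.
* **Promoters**: default 1100 nt (nominally −1000..+100 around a TSS — the
  true window behind published promoter scans is rarely stated, so it is a
  parameter), motif-planted and repaired like UTRs.
* **Phenotypes** (e.g. BAL cell counts, airway resistance): slope × mean
  dCp of coupled genes + Gaussian noise; noise-free coupling yields
  Spearman ρ = sign(slope) exactly, remembering that positive slope couples
  the phenotype to *falling* expression on the dCp scale.

## Problem sizes and calibration checks

The routine checks run at: 100 random 500-nt UTR × 10-miRNA instances for
detector-oracle equality; 1 000 random 300-nt promoters plus one 10⁶-nt
sequence for the CRE scanner; 200 replicates for ΔΔCt noise recovery
(Cp sd 0.2, n = 5/group, median fold change within 10%); all (n, m) with
n+m ≤ 10 over 100 tied datasets for exact Mann–Whitney; 200 replicates of
5 000-probe 2 × 5 null Gaussian log-ratio matrices for moderated-t type-I
error (0.05 ± 0.01 at nominal 0.05); 5 000 probes for (d₀, s₀²) recovery
(d₀ = 4, s₀² = 0.05, sampling df 8); 20 random parameter points against a
quadrature oracle (1e-6 relative) plus n = 10⁴ parameter recovery (within
10%) for normexp. The null calibration uses Gaussian matrices because the
moderated-t sampling theory is a Gaussian-error result; the generator's
exponential spot noise is exercised separately end-to-end.

## Known limitations

* Seed-match detection is a stand-in for production prediction algorithms:
  no thermodynamics, conservation, context scores, 3′-compensatory or
  bulged sites. Consensus counts over it measure the consensus machinery,
  not prediction accuracy.
* The moderated-t estimator assumes a common residual df across probes in
  its vectorized path (per-probe df vectors are accepted but arise only
  with missing data, which the array model here does not produce).
* The exact Mann–Whitney switches to the asymptotic branch above n+m = 12;
  at the boundary the two disagree by design (one is exact), so group
  sizes straddling the cut-off should not be compared across branches.
* Amplification-efficiency correction (non-2 base), standard-curve
  quantification and outlier-Cp detection are out of scope for the qPCR
  stage.
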
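# Methods

## Simulation model

A phenotype is simulated as **P = G + E** per trait. **G**, the genetic
value, is the exact sum of per-QTN contributions under three effect models
on the −1/0/+1 genotype coding (0 = heterozygote): additive a·g, dominance
d·(1−|g|), and additive×additive epistasis e·g₁g₂ for a marker pair. **E**
is multivariate-normal noise with per-trait variance calibrated from the
target heritability and optional cross-trait correlation. The model
deliberately dichotomises trait variance into these two sources only: there
is no background polygenic term, no G×E, and no non-genetic covariates.

Assumptions worth stating explicitly:

* markers are biallelic; multiallelic, monomorphic and all-missing markers
  are dropped at read time (counted, logged);
* missing genotype calls are mean-imputed to 0 (the heterozygote code)
  before effect computation, so genetic values are defined for every
  individual;
* LD is composite LD — the Pearson r of coded genotype scores — because
  diversity-panel data carry no phase; it is signed, not r².

## Architectures

* **single_trait / pleiotropy** — one QTN set sampled without replacement
  from the MAF-eligible markers; identical for every trait. Genetic
  correlation between traits arises indirectly from assigning different
  effect-size lists to the shared QTNs.
* **partial_pleiotropy** — one shared set plus disjoint trait-specific
  sets, all sampled without replacement in a single draw so no marker
  serves two roles in a replicate.
* **spurious_pleiotropy** — defined for exactly two traits. For each QTN
  slot a linking marker is drawn; its nearest qualifying upstream
  neighbour becomes the trait-1 QTN and nearest qualifying downstream
  neighbour the trait-2 QTN, with |r(link, QTN)| ≤ the `ld` ceiling for
  both. "Qualifying" means: inside the MAF window, unused, on the same
  chromosome, within a 50-marker scan window; among qualifiers the one with
  |r| *closest to the ceiling from below* is taken, so the realised LD is as
  informative as the bound allows while "maximum LD" stays a bound, never a
  target. In `direct` mode the bound applies to the QTN pair itself. The
  realised r values (link↔QTN per trait and QTN↔QTN) are recorded in the LD
  summary table. Spurious mode supports additive QTNs only: the flank-search
  semantics of a dominance or epistatic "slot" are not well defined, and the
  architecture's purpose — a misleading association peak — is additive in
  nature. After 500 failed linking draws the selection aborts with a
  configuration error suggesting a larger ceiling.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `add_QTN_num` / `dom_QTN_num` / `epi_QTN_num` | QTNs per trait (epistatic counts *pairs*); shared counts under partial pleiotropy | 0 |
| `*_QTN_specific` | per-trait private counts (partial only) | 0 per trait |
| `h2` | target heritability per trait, in (0, 1] | required |
| `cor` | target genetic correlation matrix Σ′ | none (no transform) |
| `cor_res` | residual correlation matrix | identity |
| `ld` | ceiling on \|r\| in spurious mode, in (0, 1] | 0.7 |
| `type_of_ld` | `indirect` (link-mediated) or `direct` (QTN–QTN) | indirect |
| `maf_above`, `maf_below` | MAF window, strict bounds | 0, 0.5 (vacuous) |
| `vary_QTN` | resample QTNs per replicate | false |
| `rep` | number of replicates (experiments) | 1 |
| `seed` | root seed for all randomness | 0 |

Effect sizes are dimensionless (phenotype units per coded-allele unit) and
either listed per QTN or generated as the 1-indexed geometric series
base¹…baseⁿ, largest effect to the first-sampled QTN.

MAF window bounds are strict, with one carve-out: `maf_below = 0.5` is
inclusive, since 0.5 is the maximum attainable MAF and the (0, 0.5) window
is documented as vacuous on polymorphic data.

## Correlation transform

The whitening/coloring step uses the **sample** correlation Σ of the
centred/scaled genetic values: X = L⁻¹Yᵀ with Σ = LLᵀ, then Y′ = L′X with
Σ′ = L′L′ᵀ, then each column's original mean and standard deviation are
restored. Using the sample Σ makes recovery exact (tests assert 1e−10) in
every replicate rather than asymptotic. Failure modes are reported by
name: a zero-variance trait or collinear genetic values (Σ not positive
definite) versus an infeasible target (Σ′ not positive definite). With one
trait the transform is the identity. Note the transform is only
well-conditioned when the trait columns are not nearly collinear; traits
built from identical QTN sets with near-proportional effect lists can lose
several digits of exactness.

Residual correlation is handled separately in the noise model (error terms
are independent across traits by default), so `cor` shapes the genetic
values and `cor_res` the errors.

## Heritability calibration

var_e = var_g·(1 − h²)/h², with var_g the ddof-1 sample variance of the
replicate's (post-transform) genetic-value column. This tracks each
replicate's realised genetic variance, making the realised
h² = var_g/(var_g + var_e) unbiased per replicate up to the sampling noise
of the error draw; over 1,000 replicates at n = 280 the mean realised h²
recovers the target within 0.02. At h² = 1 the error column is exactly
zero (not merely small), so phenotypes equal genetic values bitwise.

## Randomness and reproducibility

All randomness derives from one root seed through `numpy.random.SeedSequence`
spawn keys `(replicate, stream)` with fixed stream tags (QTN selection = 0,
noise = 1, fixture generation = 2). Consequences: toggling `remove_QTN`, an
output format, or the number of replicates never perturbs another stream's
draws; identical (config, genotype, seed) reruns produce byte-identical
output directories (asserted in tests); and the seeds file written alongside
the phenotypes suffices to regenerate any replicate. With `vary_QTN: false`
every replicate reuses the replicate-0 selection stream.

## Synthetic panels

The fixture generator emulates a diversity-panel genotype matrix (the
defaults, 280 inbred individuals × 5,000 SNPs, mimic a maize association
panel at reduced marker count). Markers outside LD blocks are independent
binomial draws with per-marker allele frequency from a uniform or U-shaped
(Beta(½,½)) spectrum inside the requested MAF bounds. LD blocks use a
latent-haplotype mosaic: each gamete carries a latent 0/1 indicator per
block and marker alleles copy it with per-site flip noise ε, giving
pairwise r ≈ (1−2ε)² at haplotype frequency ½, so a constant-decay block
targets r via ε = (1−√r)/2; exponential decay instead runs the indicator as
a Markov chain so adjacent-pair correlation r decays as r^distance. Block
haplotype frequencies are drawn near 0.5 (within the MAF bounds) so the
target r is achievable; block target r must be in (0, 1) — negative
within-block targets are not generated. Realised MAFs are enforced inside
the bounds by resampling violating columns (up to 50 rounds, then an
error). The `inbred_fraction` parameter duplicates one gamete for that
fraction of individuals; at 1.0 there are no heterozygotes and dominance is
inert, which matches inbred panels — tests that exercise dominance lower it.

What the generator does **not** emulate: coalescent genealogy, demography,
selection, allele-frequency/LD correlation structure of real genomes, or
genotyping error. Tests passing on these panels therefore demonstrate the
*engine's* contracts (coding, selection constraints, calibration,
exactness), not robustness to every property of real marker data.

## Numerical and format choices

* Genotype coding direction: +1 = alt/alt in VCF; for letter formats
  without a reference (HapMap, ped) the alphabetically second allele is +1.
  The direction is recorded per marker (`allele_plus` in the numeric map
  sidecar) and all architectures are sign-symmetric under flips. HapMap
  re-export preserves the direction whenever the +1 allele sorts second,
  which generator-made panels guarantee.
* Positions are 1-based; map order is file order, validated to be
  position-sorted within each chromosome run.
* Phenotype files print floats at 17 significant digits so realised
  statistics recomputed from the files match the log to ~1e−12; provenance
  tables round displayed LD/MAF to 2–4 decimals.
* Variance explained per QTN is var(contribution)/var_p with
  var_p = var_g/h² on the pre-transform scale (the implied phenotypic
  variance); the denominator is written alongside the fraction. A zero
  denominator reports NaN rather than erroring.
* Degenerate inputs fail fast with named errors: empty MAF windows,
  infeasible QTN counts, non-positive-definite correlation targets, h² = 0,
  excluding every marker.

## Problem sizes

The bundled checks run at n = 280–500 individuals and 2,000–5,000 markers
with 100–1,000 replicates — the scale at which the stochastic contracts
(heritability recovery ±0.02, LD/MAF bounds over 100 replicates) are sharp
while the whole suite stays fast on one CPU.

## Known limitations

Plink binary (bed) and GDS inputs are not read (text ped/map is); no
phase-aware D′; no dominance×dominance or higher-order epistasis; no
per-replicate correlation targets; spurious pleiotropy is two-trait and
additive-only; the TASSEL export dialect is fixed to the v5
`<Phenotype>`/taxa/data layout and may differ cosmetically from other
tools' writers.
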
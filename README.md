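# pleiosim

Simulation of multi-trait quantitative phenotypes from real or synthetic
biallelic marker data, for benchmarking multivariate GWAS and genomic
selection methods. Traits are controlled by known quantitative trait
nucleotides (QTNs) with additive, dominance and additive×additive epistatic
effects, under three multi-trait architectures:

* **pleiotropy** — one QTN set controls every trait;
* **partial pleiotropy** — a shared QTN set plus disjoint trait-specific sets;
* **spurious pleiotropy** — the traits share *no* causal loci; instead each
  of a set of linking markers is in linkage disequilibrium (LD, Pearson *r*
  of coded genotypes) with one QTN of each trait, so an association scan
  sees an apparently pleiotropic peak at a non-causal marker.

Because every QTN, effect size and seed is recorded, the output is a ground
truth against which the power and false-discovery behaviour of multivariate
statistical methods can be measured.

## Model

Genotypes are coded g ∈ {−1, 0, +1} (0 = heterozygote). Per-QTN effects are

| model | g = −1 | g = 0 | g = +1 |
|---|---|---|---|
| additive (a) | −a | 0 | a |
| dominance (d) | 0 | d | 0 |
| epistatic (e), pair (g₁, g₂) | e·g₁g₂ | | |

Effect sizes are given per QTN or generated as a geometric series
base¹, base², …, baseⁿ over the ranked QTNs. A trait's genetic value
**g**ᵢ is the exact sum of its QTN contributions.

Genetic correlations can be imposed exactly via a whitening/coloring
transform: with Σ = LLᵀ the *sample* correlation of the centred/scaled
genetic values and Σ′ = L′L′ᵀ the target, Y′ = L′L⁻¹Y_scaled has sample
correlation Σ′ to machine precision; each trait's mean and variance are then
restored.

Heritability is calibrated per replicate: given target h², residual
variance is var_e = var_g(1 − h²)/h², and phenotype = genetic value +
N(0, var_e) errors (optionally correlated across traits via `cor_res`), so
h² = var_g/(var_g + var_e) holds by construction.

## Worked example

Simulate the canonical spurious-pleiotropy scenario — two traits, three
additive QTNs each with effects (0.2, 0.1, 0.05) and (0.3, 0.2, 0.1), both
heritabilities 0.5, linking-marker LD capped at |r| ≤ 0.7 — on a bundled
synthetic panel:

```bash
pleiosim make-fixture --n-individuals 280 --n-markers 3000 \
    --block 20:0.6 --block 25:0.6 --seed 11 --out panel.txt
pleiosim simulate --config config.yaml --out results
```

with `config.yaml`:

```yaml
geno_file: panel.txt
geno_format: numeric
architecture: spurious_pleiotropy
ntraits: 2
add_QTN_num: 3
add_effect: [[0.2, 0.1, 0.05], [0.3, 0.2, 0.1]]
h2: [0.5, 0.5]
ld: 0.7
type_of_ld: indirect
maf_above: 0.05
maf_below: 0.45
rep: 5
vary_QTN: true
seed: 20
remove_QTN: true
output_format: [gemma, wide_table]
```

This prints

```
wrote 280 x 3000 panel to panel.txt
wrote 18 files to results
trait 1: mean realised h2 = 0.5146 (target 0.5)
trait 2: mean realised h2 = 0.4944 (target 0.5)
```

— the realised sample heritabilities fluctuate around the 0.5 target
(single-replicate sampling noise at n = 280). `results/` then contains
per-replicate phenotype files (GEMMA's headerless whitespace format and a
taxa-indexed table), the simulation log, the seed file, and the provenance
tables. The LD summary shows, per linking slot, the realised |r| between
the linking marker and each trait's QTN — always at or below the 0.7 input
ceiling:

```
Replication  Marker causing LD  input LD (absolute value)  Actual LD with QTN of Trait 1  Actual LD with QTN of Trait 2  QTN for Trait 1  QTN for Trait 2  LD between QTNs
1            snp_000238         0.7                        0.14                           0.15                           snp_000237       snp_000261       -0.08
1            snp_000988         0.7                        0.63                           0.69                           snp_000986       snp_000993       0.67
```

Because `remove_QTN: true`, a copy of the marker data without the causal
SNPs (linking markers retained — they are the discoverable signal) is
written for downstream GWAS. The same run with the same seed reproduces
every output file byte for byte.

The library API mirrors the CLI (`pleiosim.make_fixture`,
`pleiosim.create_phenotypes`, `pleiosim.simulate_traits`, …); see
`docs/methods.md` for the underlying model and design choices.

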
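# staarlite

Annotation-weighted, gene-centric rare-variant association testing for
dichotomous traits, with safeguards for ultra-rare-variant aggregates.

## The problem

Gene-based tests aggregate rare variants (in-sample MAF < 1%) within a gene
and functional category — pLoF, disruptive missense (DS), pLoF+DS, missense,
synonymous, and a panel of non-coding categories — and test the aggregate
against a binary phenotype with three complementary score tests:

* **burden**: `Q_B = (wᵀS)² / (wᵀΣw)` against χ²₁, with `S = Gᵀ(y − μ̂)` the
  score vector of a fitted null model and `Σ = GᵀPG` its null covariance;
* **SKAT**: `Q_S = Σⱼ (wⱼSⱼ)²` against the mixture `Σᵢ λᵢ χ²₁` given by the
  eigenvalues of `diag(w) Σ diag(w)` (Davies' inversion, Liu fallback);
* **ACAT-V**: a Cauchy combination of single-variant p-values for variants
  with MAC ≥ 10, plus one pooled burden p-value over the ultra-rare
  remainder (MAC < 10).

Each test runs under two Beta(MAF) weight settings, (1,25) and (1,1), and
across annotation channels: a MAF-only channel plus one channel per
PHRED-scaled functional score (aPC1–aPC9, CADD, LINSIGHT, FATHMM-XF), where
the variant weight is multiplied by the score percentile `1 − 10^(−PHRED/10)`.
All resulting p-values are pooled into an omnibus p-value (STAAR-O style) by
the Cauchy combination `T = Σ wᵢ tan((0.5 − pᵢ)π) / Σ wᵢ`,
`p = 1/2 − arctan(T)/π`.

This construction misbehaves on ultra-rare aggregates. When every variant in
a set has MAC < 10, ACAT-V *is* the burden test, so the omnibus pool counts
the burden evidence twice; singleton-driven sets can reach extreme
significance on the strength of one carrier; LINSIGHT (a non-coding
constraint score) can drive coding aggregates; and the missense omnibus
silently pools in the same gene's DS channel p-values, so a missense "hit"
can be a repackaged ultra-rare DS signal that no leave-one-variant-out test
supports. `staarlite` implements the five corresponding refinements as a
switchable `legacy` / `modified` mode:

1. the cumulative minor-allele count (cMAC) is attached to every output row;
2. LINSIGHT channels are excluded from coding aggregates;
3. ACAT-V is excluded when the ultra-rare subset is non-empty with cMAC < 10;
4. ACAT-V is excluded when the set is entirely ultra-rare (cMAC of the
   ultra-rare subset equals the set cMAC);
5. the missense omnibus no longer pools the gene's DS channels.

The null model is logistic (or linear) in covariates, optionally with a
polygenic random effect `b ~ N(0, τK)` for a sparse kinship matrix `K`,
fitted by PQL with average-information REML updates.

## Worked example

```python
from staarlite import AnalysisConfig, StaarModel, make_fixture

fx = make_fixture("phlda1_like", n_samples=4000, seed=0)  # pathological gene
model = StaarModel(fx.block, fx.annotations, fx.phenotype, ["risk"])
print(model.fit(mode="legacy").table[["category", "n_snv", "cmac", "staar_o"]])
print(model.fit(mode="modified").summary())
```

The fixture is a 12-SNV missense aggregate whose association signal lives
entirely in two ultra-rare DS variants (combined MAC 5, all carriers cases).
The legacy fit prints

```
   category  n_snv  cmac      staar_o
         DS      2     5 1.205362e-48
pLoF_and_DS      2     5 1.205362e-48
   missense     12    86 2.410724e-48
```

— the missense aggregate looks genome-wide significant because its pool
absorbs the DS channel p-values. The modified fit prints

```
Annotation-weighted rare-variant omnibus scan
==============================================
mode:                 modified
family:               binary
samples:              4000
variance component:   tau = 0
aggregates tested:    3
rare MAF threshold:   0.01
ultra-rare MAC <      10
significant (p < 1e-07): 2
suggestive (p < 1e-06):  2

top aggregates (gene, category, n_snv, cMAC, STAAR-O):
  PHLDA1L      DS               2      5 1.481e-48
  PHLDA1L      pLoF_and_DS      2      5 1.481e-48
  PHLDA1L      missense        12     86 1.670e-03
```

— the missense omnibus collapses from `2.4e-48` to `1.7e-03`, and the DS
aggregate that actually carries the signal now advertises its cMAC of 5:
below the reporting threshold of 10, so `results.save(path)` filters it from
the results file and logs the exclusion. `results.lovo("PHLDA1L",
"missense")` shows no single-variant removal changes the modified p
materially — the leave-one-variant-out pattern that exposes such artifacts.

A CLI wraps the same pipeline for shell use:

```bash
staarlite simulate --out-prefix sim --n-samples 4000 --n-genes 10 --seed 1
staarlite test --genotypes sim.vcf --annotations sim.annotations.csv \
    --pheno sim.pheno.tsv --covariates sex,pc1 --mode modified --out results.tsv
staarlite lovo  ... --gene GENE0003 --category missense --out lovo.tsv
```

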
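# armipop

Population genetics of the cotton bollworm (*Helicoverpa armigera*)
invasion of the Americas.

After *H. armigera* was detected in Brazil in 2013 it spread across
South America and northward within a few years. Two questions organise
the analysis this package implements, for researchers studying the
genetics of biological invasions and for anyone who wants a scriptable,
reproducible version of the classic mtDNA/nuclear-marker toolbox:

1. **Where did the invasion come from?** Rejection-based Approximate
   Bayesian Computation (ABC) compares two-population coalescent
   scenarios (Americas vs. a candidate source continent), each in three
   demographic flavours — constant size, exponential growth, and very
   rapid (instantaneous) population expansion — and reports posterior
   model probabilities.
2. **What happened after it arrived?** The complete descriptive layer:
   haplotype and nucleotide diversity, Tajima's *D* and Fu's *F*s with
   coalescent p-values, mismatch-distribution demography, hierarchical
   AMOVA with Φ-statistics, Weir–Cockerham *F*-statistics, Hardy–Weinberg
   and linkage-disequilibrium testing for codominant nuclear loci,
   rarefied allelic richness, and an ITS1 amplicon-length screen for
   putative *H. armigera* × *H. zea* hybrids.

## The statistics at the core

For a haplotype spectrum with relative frequencies *p<sub>i</sub>* in a
sample of *n* sequences, haplotype diversity is Nei's unbiased
estimator

&nbsp;&nbsp;Ĥ = n(1 − Σ p<sub>i</sub>²)/(n − 1),

with sampling variance
V(Ĥ) = [2/(n(n−1))]{2(n−2)[Σp<sub>i</sub>³ − (Σp<sub>i</sub>²)²] + Σp<sub>i</sub>² − (Σp<sub>i</sub>²)²}.
Nucleotide diversity π is the mean per-site proportion of pairwise
differences after complete deletion of gapped/ambiguous columns;
Watterson's θ<sub>W</sub> = S/a₁ with a₁ = Σ<sub>i<n</sub> 1/i. Tajima's
*D* contrasts π and θ<sub>W</sub>; Fu's *F*s is the logit of the Ewens
tail probability Pr(K ≥ k<sub>obs</sub> | θ̂<sub>π</sub>). The mismatch
distribution is fitted to the sudden-expansion model
F<sub>i</sub>(τ, θ₀, θ₁) of Rogers & Harpending by least squares, with
SSD and Harpending's raggedness r assessed by parametric bootstrap.
AMOVA decomposes squared pairwise differences into hierarchical
variance components (Φ<sub>ST</sub>, Φ<sub>CT</sub>, Φ<sub>SC</sub>);
nuclear loci get the Weir & Cockerham (1984) estimators θ̂ = F<sub>ST</sub>,
f̂ = F<sub>IS</sub>, F̂ = F<sub>IT</sub> from per-allele variance
components, Guo & Thompson's Markov-chain exact HWE test, and an
EM-based likelihood-ratio test of gametic disequilibrium.

The coalescent simulator is infinite-sites with θ = 4N₀µ per locus and
time in units of 2N₀ generations; the ABC layer standardises summary
statistics (π, S, D, π within and between demes) by their
reference-table spread, retains the nearest fraction of simulations by
Euclidean distance, and scores candidate statistic subsets by how often
they recover the true model of pseudo-observed datasets.

## Worked example

The package embeds the published 54-haplotype × 7-region count table
(303 concatenated COI+COII+Cyt *b* sequences) as a code fixture, so the
headline diversity numbers are reproducible in a few lines:

```python
import armipop as ap

spec = ap.table1_fixture()
for region in [None, "AM", "CE/CA", "Puerto Rico"]:
    hd, sd = ap.haplotype_diversity(spec, region)
    n = spec.sample_size(region)
    k = int((spec.column(region) > 0).sum())
    print(f"{region or 'Total':12s} n={n:<4d} k={k:<3d} Hd={hd:.3f} +/- {sd:.3f}")

ne = ap.ne_from_theta(4.123, 0.0115e-6, 626)
print(f"Ne = {ne:,.2f}")
print(f"tau = {ap.tau_from_generations(3_750_000, ne):.3f}")
```

prints

```
Total        n=303  k=54  Hd=0.926 +/- 0.006
AM           n=16   k=12  Hd=0.958 +/- 0.036
CE/CA        n=124  k=33  Hd=0.915 +/- 0.012
Puerto Rico  n=4    k=2   Hd=0.667 +/- 0.204
Ne = 572,718.43
tau = 3.274
```

— the total sample of 303 sequences collapses to 54 haplotypes with
high diversity (Ĥ = 0.926), similar across regions, and the per-locus
θ<sub>W</sub> = 4.123 calibrates an effective size of ~572,700 and a
maximum coalescence age of 3.274 (in units of 2Ne generations) for the
ABC priors.

A desk-scale ABC run against a pseudo-observed rapid-expansion dataset:

```python
import numpy as np, armipop as ap

rng = np.random.default_rng(7)
models = [ap.ModelSpec(name=f, family=f) for f in ("constant", "growth", "expansion")]
table = ap.build_reference_table(models, 500, rng)
pod, truth = ap.gen_pods(models[2], 1, rng)[0]
res = ap.rejection(pod, table, tolerance=0.02)
print({k: round(v, 1) for k, v in res.posterior_probabilities.items()})
print("best:", res.best_model())
```

prints

```
{'constant': 16.7, 'growth': 16.7, 'expansion': 66.7}
best: expansion
```

— the retained simulations are dominated by the expansion family, so
its posterior probability (reported on the 0–100 scale) is highest, and
the generating family is recovered.

There is also a command-line interface (`armipop diversity|neutrality|
mismatch|amova|nuclear|abc|hybrids|synth|run`); `armipop run --config
run.toml` drives any subset of the pipeline from one TOML file with a
single master seed and writes TSV/JSON reports plus a provenance log.

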
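# Methods

This note documents the models, estimators, numerical choices and known
limitations of `armipop`, in the order the pipeline runs.

## Data model and site filtering

All sequence statistics operate on an `Alignment` after **complete
deletion**: any column containing a gap or IUPAC ambiguity code in any
sequence is removed alignment-wide, and the effective length L is the
number of surviving columns. The source analyses do not state how
indels/ambiguities were handled before haplotype collapsing; complete
deletion is our documented choice because it makes every count
reproducible from the input file alone and matches the default of the
classic sequence-analysis programs this layer mirrors. Haplotype ids
are assigned in descending total frequency with ties broken by first
occurrence, so collapsing is deterministic given input order.

Genotypes are unordered allele-size pairs stored sorted; missing data
are excluded locus-wise (pairwise deletion). Coordinates are 0-based
half-open. FASTA headers may carry `id|site|region`; a metadata sidecar
TSV wins on conflict.

## Diversity estimators

Haplotype diversity uses Nei's unbiased estimator and his exact
variance formula (both reproduce the published ± cells from counts
alone, which is the package's primary numeric cross-check). Nucleotide
diversity is the mean per-site pairwise difference over the
complete-deletion length; its standard deviation combines sampling and
stochastic variance (Tajima's formula), V(π) = (n+1)π/(3(n−1)L) +
2(n²+n+3)π²/(9n(n−1)). Watterson's θ is reported **per locus** by
default because the per-locus value (4.123 for the 626-bp COI set)
feeds the prior calibration; a per-site variant is exposed.

The calibration arithmetic is reproduced exactly as printed: Ne =
θ/(rate·L) with no ploidy factor (the mtDNA convention would insert a
factor 2), and τ = generations/(2Ne). We implement the printed
arithmetic rather than "correcting" it; the discrepancy is noted here.

## Coalescent simulator and time scale

The simulator is a standard backward-time structured coalescent with
infinite-sites mutation: deme of relative size x coalesces each lineage
pair at rate 1/x; mutations are Poisson(θ·T_total/2) on the realized
tree and fall on branches proportionally to length. These two rules
give E[pairwise differences] = θ and E[S] = θ·Σ1/i (verified against
analytic values and against msprime in the test suite). **The implied
time unit is 2N₀ generations** — with pair rate 1, E[T₂] = 1 unit = 2N₀
generations. This is convenient here because the calibrated maximum
coalescence age τ = generations/(2Ne) = 3.274 is already on this scale
and is used unconverted as the divergence-time prior maximum.

Three demographic families implement the scenario set:

* **constant** — all demes at relative size 1;
* **growth** — relative size e^(−αt) backward in time, with the
  exponential regime spanning the divergence (the ancestral population
  continues the same trajectory); α ~ U(0.05, 2.5], capping total
  growth over the 3.274-deep window at ≈3600×, the same magnitude range
  as the expansion family — steeper rates degenerate into instantaneous
  collapse and are not a distinct hypothesis;
* **expansion** — instantaneous size drops (backward) bracketing the
  divergence: one at f₁·min(t_div, w) (the invading deme's
  founder-to-outbreak expansion) and one at t_div + f₂·w (the source
  population's expansion shortly before the split), with w = 0.5 time
  units ≈ Ne generations and size ratios ~ U(0.001, 0.1] (ten- to
  thousand-fold expansions). Tying event ages to the recent epoch,
  rather than letting them float over the whole tree depth, is what
  makes this family mean "very rapid recent expansion": a size change
  deeper than the sample's coalescent window leaves no signature in any
  summary statistic and would make the hypothesis vacuous.

No migration is modelled in any family. Two demes at most; sample
sizes default to 36 + 40 (the Americas-vs-source design) and L = 626 bp.

`simulate_fixed_s` conditions on the observed number of segregating
sites (mutations placed uniformly on the realized tree) and is the null
for neutrality-test p-values; the known slight negative bias of fixed-S
nulls for Tajima's D is covered by a test. `realize_sequences` maps 0/1
sites onto nucleotides with a configurable base composition (default
AT-rich, as in insect mtDNA) and a transition bias (default 0.9).

## Neutrality tests and mismatch demography

Tajima's D uses the standard constants; S = 0 raises a typed
`UndefinedStatisticError` rather than propagating NaN. Fu's Fs computes
S′ = Pr(K ≥ k_obs | θ̂_π) under the Ewens sampling formula via a
Bernoulli convolution (K is a sum of independent "new type" indicators
with success θ/(θ+i−1)), which is numerically stable at n = 303 where
Stirling-number arithmetic overflows; k_obs = 1 gives S′ = 1 and is
signalled as a degenerate +∞, never written to tables as a float.

P-values for both statistics are **one-tailed (lower)**, matching the
convention of reporting significantly negative values, with the
(b+1)/(B+1) correction; the null conditions on observed n and S
(fixed-S), with a fixed-θ mode available.

The sudden-expansion model F_i(τ, θ₀, θ₁) is fitted by SSD
minimisation: a coarse grid (τ up to twice the class range, θ₀ in
0.01–5, θ₁ up to 10⁴ — the cap stabilises the fit, since θ₁ → ∞ is an
equilibrium plateau) followed by bounded Nelder–Mead. SSD and
raggedness p-values and the τ interval come from a parametric bootstrap
under the fitted model; the mutational age τ maps to a simulator event
time τ/θ₁ (2N-generation units). Raggedness is r = Σ(x_i − x_{i−1})²
with a zero class appended past the last observed class, so a point
mass at zero differences gives r = 1 and the maximum is 2. The
published "τ (SD 95%)" column heading is an interval, not an SD; we
emit a percentile interval and label it as such.

## AMOVA and pairwise Φ_ST

Distances are plain pairwise difference counts — the "gamma = 0"
setting of the referenced program, i.e. no rate-heterogeneity
correction — and the decomposition follows the standard sums of squared
differences with unequal-sample-size coefficients (n, n′, n″ at three
levels). Negative variance components are reported as estimated and
enter the percentage normalisation, as in the published table that
prints a small negative among-regions component. Each Φ has its own
permutation scheme: individuals among sites (Φ_ST), whole sites among
regions (Φ_CT), individuals among sites within regions (Φ_SC); p =
(b+1)/(B+1). When every region holds exactly one site the
within-region/among-site stratum is empty and σ_b is fixed at 0, which
makes the 3-level Φ_ST collapse to the 2-level value exactly. Pairwise
Φ_ST cells are two-population AMOVAs; negative estimates are retained.

## Nuclear-marker statistics

H_E is unbiased over 2n genes; H_O the heterozygote fraction. The HWE
test walks genotype tables with the observed allele counts by swapping
one allele between two random individuals per step — a symmetric
proposal on allele-to-individual assignments whose stationary law is
exactly the Levene/Haldane conditional distribution, so every proposal
is accepted (the Metropolis ratio is identically 1) — and estimates
p = Pr(table no more probable than observed), with a batch-mean
standard error; defaults are 10,000 dememorisation steps, 1,000 batches
of 10,000 iterations (the cited protocol), and a warning is emitted if
the SE reaches 0.01. A full-enumeration biallelic oracle backs the
chain in tests. Fisher's method combines per-locus p-values. The
Weir & Cockerham (1984) estimators are computed from per-allele
variance components summed over alleles and loci; θ is tested by
permuting individuals among populations and f by re-pairing gene copies
within populations. The identity (1−F) = (1−f)(1−θ) holds exactly for
the summed components and is asserted in tests. Rarefied allelic
richness uses the hypergeometric expectation Σ[1 − C(N−N_i, g)/C(N, g)]
with g defaulting to the smallest per-population gene count. The LD
test estimates two-locus haplotype frequencies by EM (phase unknown)
and compares against the allele-frequency-product null by likelihood
ratio, with significance from permuting one locus across individuals.

## ABC pipeline

Summary statistics: pooled per-site π, pooled S, pooled Tajima's D,
per-deme π_w, and between-deme π_b. A simulated S = 0 leaves D
undefined; it is encoded as 0 with a validity flag carried outside the
candidate set so vectors stay fixed-length. Distances are Euclidean on
statistics standardised by the reference-table standard deviation (the
rejection program the design follows does not document its scaling;
ours is recorded in output metadata, and zero-variance statistics are
dropped with a warning). PP is each model's share of the retained
ceil(tolerance·rows) simulations, reported ×100. PP ties are broken by
the smaller mean retained distance.

Vector selection withholds 10 rows per model as pseudo-observed
datasets and scores every subset of ≥2 statistics by correct argmax-PP
classifications; ties prefer fewer statistics, then lexicographic
order. Goodness of fit projects the standardised observed vector on
the reference PCA axes and reports the Mahalanobis percentile (inside
if ≤0.95). Prior restriction takes Epanechnikov-weighted 2.5/97.5%
quantiles of the retained draws (w_i = 1 − (d_i/d_max)²; all-equal
distances fall back to plain percentiles); "weighted values" in the
source description is interpreted as this kernel, the convention of the
cited toolkit, and an unweighted mode exists. The hierarchical
comparison builds a fresh reference table over each scenario's best
model and repeats rejection.

Priors are uniform. θ ~ (0, 4.123] (the observed per-locus Watterson
estimate as maximum); t_div ~ (0, 3.274]; the expansion/growth
parameters as above. Lower bounds are small positive numbers since the
sources state only maxima. Desk-scale defaults are 2,000–10,000
simulations per model; the published 300k/900k/3M scales are reachable
through the same API and all counts are recorded in outputs.

## Hybrid screen

Amplicon lengths near 147 bp (H. armigera) and 334 bp (H. zea) within a
±10 bp gel tolerance (our declared default; the sources do not state a
size-calling tolerance) classify single-band individuals; a double-band
individual is a putative hybrid only when sequencing confirms each band
as its expected species, and any nonspecific or cross-species
confirmation yields "indeterminate". Frequency is 100×hybrids/total,
printed to one decimal.

## Synthetic data

The generator module is the test substrate and defines the study
conditions:

* `table1_fixture` embeds the published per-region haplotype counts
  (sizes 16/22/124/52/56/29/4, total 303, 54 haplotypes) as constants;
  `table1_alignment` realises them as sequences in which each haplotype
  carries a private diagnostic site — the frequency structure is exact,
  the genealogy deliberately is not.
* `gen_mtdna_dataset` simulates a single panmictic rapid expansion
  (defaults τ = 3.5, θ₀ = 1, θ₁ = 100 — the mutational age the mismatch
  analysis reports and a hundred-fold expansion) and labels individuals
  with the published region sizes, two sites per region. Panmixia
  matches the system's observed lack of spatial structure; consequently
  synthetic AMOVA components are near zero by construction and the
  generator cannot exercise detection of real structure.
* `gen_genotype_table` draws three loci (two many-allele, one nearly
  monomorphic, mimicking the EPIC panel's behaviour) at a target F_IS
  (default 0.13, the published multilocus estimate) via
  P(hom i) = p_i² + F·p_i(1−p_i).
* `gen_pods` draws pseudo-observed SuSt vectors with recorded truth.

What passing tests on these data do **not** show: performance under
real base-composition heterogeneity, rate variation among sites,
sequencing error, null alleles at nuclear loci, or migration — none of
which the generators emulate.

## Numerical choices and edge cases

Permutation and bootstrap p-values all carry the +1 correction and
respect the 1/(B+1) floor. All chains, permutations and simulations
take explicit seeds; a master seed derives per-stage seeds
deterministically in the CLI, and identical configurations produce
byte-identical reports. Monomorphic inputs: diversity 0, Φ reported 0
with all components 0, HWE p = 1 flagged "not testable", LD "not
testable". Degenerate covariance in the goodness-of-fit PCA falls back
to the available axes with a flag. The Ewens convolution floors S′ at
1e−300 before the logit.

## Problem sizes in tests

The suite runs the analytic coalescent calibrations at 20,000
replicates, family-reduction KS checks at 3,000, the D-null calibration
at 2,000, and ABC model recovery with 2,000 simulations per model and
50 pseudo-observed datasets; oracle-equality checks (AMOVA, W&C, HWE
enumeration) use ≤50-individual instances where exact computation is
feasible. These sizes were chosen so the full suite completes in about
a minute on one core while keeping Monte-Carlo noise well inside the
asserted tolerances.

## Known limitations

* Rejection ABC only — no regression adjustment, no random-forest ABC,
  and no migration models (excluded by design).
* The three demographic families genuinely overlap: a weak expansion, a
  mild growth curve and a constant population are not distinguishable
  from a 626-bp locus, and posterior probabilities near 40–50 for the
  winning model are the expected regime, not a failure mode.
* The mismatch fit's θ₁ cap (10⁴) means "effectively infinite"
  post-expansion size; τ̂ near the grid edge flags a non-informative
  observed distribution.
* The HWE chain's batch-mean SE underestimates autocorrelation for very
  short batches; the defaults keep batches long enough that the SE
  bound (0.01) is meaningful.
* The ITS1 classifier trusts per-band confirmations; it does not model
  band-calling error beyond the ±10 bp tolerance.
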
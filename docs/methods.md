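# Methods

`hybridcensus` decides, bird by bird, whether members of a hybridized
captive population are pure representatives of a focal species or carry
donor-species introgression, and produces a defensible census of the pure
group. The setting it targets is a two-species problem: a bottlenecked
focal species A (few alleles per microsatellite locus, no reference
sample of guaranteed purity) hybridized with a diverse donor species B
(known-pure reference birds available), with hybridization running
through F1/F2 generations and repeated backcrosses toward A only, and
with all donor-side matings through donor females (so mtDNA marks
maternal-side introgression of any age).

## Admixture model

The core engine is a Bayesian admixture model of the classic
Pritchard-Stephens-Donnelly form. Each allele copy of individual *i*
carries a latent cluster of origin `Z`; cluster *k* holds per-locus
allele frequencies `P[k]`; individual *i* has an admixture vector
`q_i ~ Dirichlet(alpha)`. A Gibbs sweep updates `Z | P, q` (per-copy
categorical), `q | Z` (Dirichlet with origin counts), and `P | Z`
(Dirichlet with allele counts); missing genotypes are skipped everywhere.
The reported `q` is the posterior mean over the post-burn-in chain.

Two allele-frequency priors are available:

* **independent** — `P[k, l] ~ Dirichlet(lambda)`, `lambda = 1` by
  default;
* **correlated** (default for real-data clustering) — cluster frequencies
  are tied to a latent ancestral vector `P_anc[l]` through per-cluster
  drift parameters `F_k`: `P[k, l] ~ Dirichlet(P_anc[l] (1-F_k)/F_k)`.
  `P_anc` is updated by a per-locus Metropolis step with a
  Dirichlet-proposal centred on the current value; `F_k` has a uniform
  (0,1) prior and a reflected random-walk update.

`alpha` is by default sampled by a Metropolis step with a uniform prior
on (0, 10]; pinned individuals are excluded from that update.

**Prior-population-information mode** (`use_popinfo`): individuals whose
origin is declared known have `q` pinned to their cluster and contribute
all allele copies to that cluster's frequency estimate. The additional
switch `freqs_from_flagged_only` restricts the `P` updates to flagged
individuals, which mirrors protocols where reference samples "are used to
estimate allele frequencies" and candidates are scored against them.

**Correctness.** The sampler is checked against a brute-force oracle: on
instances small enough to enumerate every `Z` configuration (3
individuals, 2 loci, 2 alleles, K=2, fixed alpha, independent prior),
`P` and `q` integrate analytically to Dirichlet-multinomial weights and
the exact marginal mean `q` is a finite sum. Sampler and oracle agree to
total variation < 0.02 (typically ~0.002) in the test suite.

### Settings for simulated-class scoring runs

Power tables and simulated-class scoring use three deliberate deviations
from the real-data defaults, all config-exposed:

1. `freqs_from_flagged_only = True`. A scoring batch is mostly admixed;
   letting it feed the cluster frequencies pulls the clusters together
   and shrinks every `q` toward 0.5.
2. `freq_model = "independent"`. The correlated prior couples the two
   clusters' frequency estimates through `P_anc`; at anchor sizes of a
   few dozen birds this compresses their separation and inflates the mean
   `q` of backcross classes by ~0.04.
3. `alpha` fixed at 0.2 rather than sampled. The class composition of a
   simulated batch (e.g. 100 birds per class) is a design artifact, not a
   population sample, so the admixture hyperprior is not estimable from
   it; sampling alpha there converges to ~0.5 and imposes a floor of
   `alpha / (2 alpha + 2L)` ≈ 0.017 on every `q`, which caps pure-bird
   assignment below a 0.99 threshold. At `alpha = 0.2` the prior carries
   0.4 pseudo-copies against 28 observed allele copies — weak enough to
   be data-dominated, strong enough to regularize.

With these settings the mean `q` toward the donor per simulated class
tracks the pedigree expectations (F1 0.5, backcrosses 0.25, 0.125,
0.0625) within Monte-Carlo error, and detection percentages decline
monotonically with backcross depth — the behavior the framework's
threshold calibration relies on.

## K selection and replicate alignment

The number of clusters is chosen by the Evanno delta-K rule on replicate
mean log-likelihoods: `delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))`,
maximized over interior K. Replicate runs are label-aligned before
averaging: each run's cluster permutation is chosen to maximize
similarity (1 − normalized Frobenius distance) with the first run, then
refined against the evolving consensus until stable; exhaustive over
permutations, so limited to K ≤ 6. Classification is by threshold on `q`
toward the focal cluster (resolved as the cluster the donor anchors do
not own); the boundary value counts as pure.

## Genotype-frequency-class model

Hybrid categories that share an expected ancestry (F1 vs F2) differ in
the expected proportions of loci with 0/1/2 donor allele copies; each
class is a triple `phi = (phi_AA, phi_AB, phi_BB)`. The default set is
pureA (1,0,0), pureB (0,0,1), F1 (0,1,0), F2 (.25,.5,.25), BxA (.5,.5,0),
BxB (0,.5,.5); the table is user-extensible. The single-locus genotype
likelihood under a class is the phi-mixture of the three ancestry-pair
laws; loci multiply.

The Gibbs sampler alternates: class membership per free individual
(categorical in `pi` × likelihood), per-locus ancestry-pair states given
the class, allele-copy attribution to species (heterozygote orientation
sampled by relative likelihood), species frequencies
`theta ~ Dirichlet(prior + attributed counts)`, and mixing proportions
`pi ~ Dirichlet(prior + class counts)`. z-fixed individuals never change
class but feed the `theta` updates. Priors: Uniform = Dirichlet(1);
Jeffreys = Dirichlet(1/2) for `pi` and Dirichlet(1/n_alleles) per locus
for `theta`. Alleles unseen in a species get pseudo-frequency from the
prior rather than hard zeros. `fixed_pi` pins the mixing proportions,
which is how the MCMC is compared to the closed-form posterior (with
`pi` free, the model is an empirical-Bayes mixture and legitimately
sharper than a fixed-prior calculation). A bird is assigned to a class
when a single class reaches the 70% posterior cutoff; for power
bookkeeping a hybrid simulant is "correct" if its call is any non-pure
class, and unassigned counts as incorrect.

## Synthetic data generator

The generator's defaults are the emulated study's conditions: 14 unlinked
loci, species A with 2–5 alleles per locus, species B with 2–14,
differentiation calibrated to Weir-Cockerham FST 0.28 ± 0.03 (verified
internally by sampling 50 birds per side and computing FST; bounded
search over a divergence dial, seeded, error if unattainable).

Per locus the model is an explicit founder bottleneck: B draws a
Dirichlet frequency vector over up to 14 alleles (rare ones pruned at
2%); A's allele set descends from six founder allele copies, giving 2–5
alleles at high frequency. The divergence dial controls how many of A's
alleles are shared with B and how rare the shared alleles are in B; at
least one allele per locus is always shared, so no locus is fully
diagnostic. This reproduces the joint pattern real bottlenecked panels
show — moderate FST (the donor's diversity depresses it) together with
high per-individual assignment information — which a plain
Balding-Nichols drift model cannot: at the same FST it spreads the
divergence thinly across alleles and under-separates individuals.

Hybrid classes are simulated two ways. The *frequency* method draws each
allele of a genotype independently from one of the class's two gamete
pools, each pool a (wA, wB) mixture of the parental frequencies; a
derived class's pool is the equal mixture of its parents' pools, so the
backcross gamete's B-weight halves each generation (0.5, 0.25, 0.125,
0.0625) and F2/F3 coincide (the allele-frequency view has no
inter-generation variance — both labels are kept for reporting
fidelity). The *pedigree* method instantiates the mating recipe
recursively (BxA2 = BxA1 × pureA, ...) with Mendelian gamete sampling,
tracks each individual's realized ancestry fraction and its maternal
line; pure-donor parents are always the dam (only donor females were
used in the emulated program), so every F1 and every descendant of a
hybrid dam carries the donor haplotype.

The full study fixture bundles 33 known-origin donor birds and 148
candidates (66 pure A, 15 F1, 12 F2, 20/20/15 backcross 1–3), morphology
labels drawn with probability logistic in true donor ancestry (slope 14,
midpoint 0.22 — sharp, as in the emulated program, where F1/F2 birds were
essentially always recognizable and only ~18% of pure-phenotype birds
proved admixed), maternal haplotypes from the pedigree, and a 311-bp
haplotype pair differing at exactly 9 positions. What the fixture does
*not* emulate: genotyping error, null alleles, allele-size homoplasy,
missing data (available via `missing_rate`, default 0), linkage, and
selection — so green end-to-end tests demonstrate the statistical
machinery under clean typing, not robustness to laboratory artifacts.

## Power tables and threshold choice

`simulate_power_table` simulates n (default 100) genotypes per class from
the anchor sets' empirical frequencies, scores the whole batch in one
joint admixture run (anchors flagged; per-class runs are also available
but a single-class batch distorts any batch-level hyperparameter), and
scores the class model per prior combination. A parental simulant is
correct if called pure toward its own cluster; a hybrid simulant is
correct if called pure toward neither. `choose_threshold` picks, among
thresholds whose focal-parental error is within the configured budget
(default 5%), the one maximizing detection of the deepest backcross,
ties toward the lower threshold.

## mtDNA diagnostics

Diagnostic sites are alignment positions (1-based) whose non-missing base
is fixed within each reference lineage and differs between them; a single
polymorphic reference sequence disqualifies a site. Lineage assignment is
by site-wise voting (N/gap votes nothing; ties are ambiguous), reported
with the match fraction. The census tabulates individuals per (group,
lineage); with two haplotypes a median-joining network is a single edge,
so a pairwise-difference matrix replaces it without information loss.

## Differentiation statistics

FST is the Weir-Cockerham variance-components estimator (theta):
per-locus, per-allele components a/b/c from sample sizes, allele
frequencies and heterozygote frequencies, multilocus theta =
sum(a)/sum(a+b+c); undefined (None) if everything is monomorphic.
Significance comes from a log-likelihood G test (allele × group per
locus, summed) with a null built by permuting whole individuals between
groups — permuting individuals rather than alleles preserves
within-individual allele association; the p-value uses the +1 correction
and is never exactly zero. Its type-I error is verified at the nominal 5%
level over 200 null datasets in the acceptance suite. The FCA ordinates
individuals by correspondence analysis (SVD of standardized residuals) of
the 0/1/2 allele-dosage table; missing loci contribute no counts and
simply lower the row mass; axis signs are fixed by making a chosen
group's mean coordinate positive.

## Pipeline

Stage 1 (stringent screen) runs both models on the morphologically pure
candidates with the donor anchored, at a 99% purity rule, intersects the
pure calls, and removes donor-mtDNA carriers; the survivors are the
pre-defined pure group. Only the donor side is anchored here, so cluster
frequencies must come from all individuals (`freqs_from_flagged_only`
off) and `alpha` is sampled (this batch *is* a population sample). Stage
2 calibrates the threshold from power tables simulated off the
pre-defined group. Stage 3 re-runs the admixture model over everyone
(morphological hybrids included) with both anchor groups flagged, using
the same model settings as the calibration runs (otherwise the threshold
does not transfer), classifies at the chosen threshold, applies the mtDNA
filter, and emits the census. Two identities are enforced on every run:
final = pre-defined + reincorporated, and final = assigned − mtDNA
excluded. Hybrid-class attribution of admixed birds compares their q to
the simulated per-class q ranges and reports overlaps rather than forcing
a label. A provenance record (input hash, seed, configs) makes runs
bit-reproducible.

## Numerical choices and problem sizes

Chains are vectorized NumPy; a full sweep over ~1,000 individuals × 14
loci costs ~3 ms. Defaults mirror common practice (10^6 iterations, 10^5
burn-in); the test and acceptance runs use 8k–50k iterations with
proportional burn-in, which this problem size mixes well within (the
acceptance checks pass at 50k against their stated tolerances). The test
suite runs the pipeline at 25 simulants per class and 3 replicates;
`scripts/acceptance.py` uses 100 per class, one 50k-iteration joint run.
Degenerate inputs are defined, not crashed on: all-missing frequency
cells report sample size 0; monomorphic datasets give FST = None; a zero
likelihood under every genotype class yields a uniform posterior with a
warning; chain non-convergence (first/second-half mean-q discrepancy
> 0.1) warns but does not error.

## Known limitations

* No null-allele or genotyping-error model; no linkage; no
  stepwise-mutation model for the microsatellites.
* The admixture model's `q` for deep backcrosses is compressed toward the
  pure corner's posterior floor; at 14 loci and FST ≈ 0.28 classes beyond
  the third backcross are not reliably separable from pure — which is the
  framework's own motivation for the simulation-calibrated threshold.
* Label alignment is exhaustive over cluster permutations (K ≤ 6).
* The class model fixes the class table (no uncertainty on phi) and
  assumes independent loci within individuals.
* With only two mtDNA haplotypes the diagnostic-site screen cannot detect
  recombination or heteroplasmy, and inputs must be pre-aligned and of
  equal length.
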
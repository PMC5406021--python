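# Methods

`invabc` reconstructs the invasion history of a recently spreading species
from two marker sets — co-dominant microsatellites and a single haploid
mtDNA locus — by simulating competing demographic scenarios under a
structured coalescent and comparing them to data with approximate Bayesian
computation (ABC). The package also carries the companion statistics used to
characterize spatio-temporal structure: diversity and differentiation
estimators, two bottleneck tests, and haplotype analysis.

## Demographic model

A *scenario* is a fixed topology of populations connected by timed events:

* **split** — backward in time, all lineages of a derived population move
  into its source at the introduction time;
* **admixture** — each lineage independently reroutes to a second source
  with probability `ra`;
* **Ne change** — a population's effective size changes at a time boundary
  (used for founder bottlenecks: a reduced-Ne epoch of duration `db`
  immediately after each introduction).

Time is measured in generations before present (present = 2015), with 10
generations per year — appropriate for a multivoltine tropical mosquito
(5–17 generations/year in the tropics). Serial (multi-year) samples enter as
tips at their collection times.

The shipped study system has six sampled regional populations — mainland SE
Asia (SEA), Indonesia (IND), Papua (PAP), Papua New Guinea (PNG), the
Solomon Islands (SOL) and the Torres Strait/southern Fly region (TSF) — plus
an unsampled ancestor (ANC) that splits into SEA and IND. Five scenarios
differ in the sources of the introduced populations; all share TSF seeded
from Indonesia, and scenarios 1 and 4 differ only in whether the Solomons
came from SEA or PNG. The alternative sources for the remaining scenarios
(PNG from Indonesia; Papua from Indonesia; stepwise SEA→PAP→PNG) are
plausible routes chosen by the package and fully overridable through the
scenario configuration, as are all priors. An optional sixth scenario models
the Solomons as a SEA×PNG admixture.

Default priors: population Ne uniform(10, 10^6); founder Ne uniform(10,
10^4) with duration uniform(0, 200) generations; introduction times
truncated-normal around first-detection years (Papua 1962, PNG 1972,
Solomons 1979, TS/Fly 2005) with order conditions (each event younger than
the previous); the ANC split loguniform over 17,900–276,000 generations
(1,790–27,600 years). Microsatellite mean mutation rates loguniform(10^-6,
10^-3) per locus per generation, di- and trinucleotide classes drawn
separately; mtDNA substitution rate uniform(7×10^-10, 10^-7) per site per
generation.

## Coalescent engine

Genealogies are simulated backward in time under the continuous-time
(Kingman) approximation: with k lineages in a population of size Ne, pair
coalescence occurs at rate k(k−1)/2 × 1/(ploidy·Ne) per generation. This is
standard and accurate for the Ne ranges involved; no generation-by-generation
Wright–Fisher simulation is performed. Each microsatellite locus gets an
independent diploid genealogy; the mtDNA locus gets one haploid genealogy
with effective size Ne/4 (haploid, maternally inherited; configurable).

**Microsatellite mutation (GSM).** Mutations are Poisson on branches
(rate × branch length). Step sizes are geometric with parameter `p_gsm`
(P(step = 1) = p_gsm, default 0.7), sign symmetric. Per-locus rates are
gamma-dispersed around the motif-class mean (shape 2 by default). Repeat
counts reflect at a lower bound of 2 repeats; the reflection is applied once
to final tip states rather than per mutation — an approximation that only
matters when a lineage wanders far below the bound, which the ancestral
state of 25 repeats makes rare. No upper allele bound or contiguous-window
constraint is enforced.

**Sequence mutation (HKY).** Per-branch transition matrices are exact matrix
exponentials of the HKY rate matrix (transition/transversion parameter
kappa, default AT-rich insect-mitochondrial base frequencies), normalized to
one expected substitution per unit time; the root sequence is drawn from the
stationary frequencies. With kappa = 1 and equal frequencies this reduces to
Jukes–Cantor, which is the configuration cross-checked against an
independent coalescent simulator in the test suite.

## Summary statistics and ABC

The default summary menu, computed identically on observed and simulated
data: per sample group — mean allele count, mean unbiased gene diversity,
mean allele-size variance (repeat units), mean Garza–Williamson M; per group
pair — Weir–Cockerham F_ST, shared-allele distance DAS, (δμ)²; for the
sequence locus — haplotype count, segregating sites, mean pairwise
differences, Tajima's D per group, and mean between-group differences plus
Hudson's F_ST per pair. Statistics undefined on a dataset (Tajima's D at
S = 0, F_ST with zero between-group diversity) are imputed 0 and masked;
masked columns and columns with zero median absolute deviation are excluded
from distances.

Scenario choice follows the rejection + multinomial-logistic construction:
retain the closest `tolerance` fraction of the reference table (Euclidean
distance over MAD-normalized statistics; default 1%), regress the scenario
label on the centred statistics, and read posterior probabilities at the
observed point (the intercepts' softmax). The fit uses an unpenalized
intercept with a weak ridge on slopes so it stays defined near separation;
95% CIs come from the delta method applied to the intercept block of the
observed-information covariance. If the fit fails, rejection proportions
with multinomial CIs are reported instead (and flagged). When the statistic
space is large the regression runs on the leading 20 principal components.

Parameter estimation uses Beaumont local-linear adjustment: weighted
regression (Epanechnikov weights by distance) of transformed parameters on
centred statistics; adjusted draws are the fit at the observed point plus
residuals, back-transformed (log for positive parameters, logit for
proportions). Confidence in scenario choice is estimated end-to-end:
pseudo-observed datasets (PODs) simulated from each scenario's prior are run
through the same rejection + logistic pipeline; type I for a scenario is the
fraction of its own PODs it loses, type II the fraction of foreign PODs it
wins. Model checking projects the observed vector (and posterior-predictive
simulations) into the PCA space of prior simulations and reports per-PC
percentiles.

## Companion statistics

Diversity per population×locus: Na, effective allele number 1/Σp², Ho,
He = 1−Σp², unbiased uHe = 2n/(2n−1)·He, fixation index F = 1−Ho/He
(undefined for monomorphic loci). Pairwise differentiation: Weir–Cockerham
θ (ratio of sums over alleles and loci); Jost's D and G″_ST from
Nei/Chesson-corrected HS and HT with the two-sample finite-sample factors,
averaging HS and HT across loci before the ratio (per-locus-ratio mean
available); Φ_PT from a two-level AMOVA over squared codominant genotypic
distances. Significance by permutation of individuals between populations,
p = (1+#{perm ≥ obs})/(n_perm+1), default 9,999 permutations; Mantel tests
correlate genetic and great-circle geographic distances with row/column
permutations. Negative estimates are reported raw.

Sequence statistics use pairwise deletion of N/gap sites. Haplotypes
collapse by exact identity or by N-tolerant compatibility with the lowest
record id anchoring each haplotype. Hd = n/(n−1)(1−Σp²);
π is the mean pairwise proportion of differing compared sites; Tajima's D
uses the standard a1…e2 constants. The haplotype network is a minimum
spanning network over Hamming distances with edges above a configurable cap
dropped (a pragmatic stand-in for statistical-parsimony connection limits —
the network is for visualization, not inference) and unsampled intermediate
nodes decorating multi-step edges.

## Bottleneck tests

**M-ratio.** Per locus M = k/(r+1) with r the allele range in repeat units
(anchored at the observed minimum; integrality of the allele lattice is
enforced), averaged across loci, flagged at the conventional 0.68 critical
value. Note that under a generalized stepwise model with a substantial
multi-step tail, equilibrium M can sit near the critical value — the 0.68
threshold presumes mostly single-step mutation.

**Heterozygosity excess.** The null distribution of gene diversity given the
observed allele count k and sample size n follows the classic fixed-k
construction: simulate coalescent genealogies with two-phase-model (TPM)
mutations — 90% single-step, multi-step sizes 2+geometric tuned so the
multi-step step-size variance equals the 0.15 setting — and keep simulations
with exactly k alleles. Two implementation points matter for calibration:

1. The proposal θ is matched so that the *simulator's own* expected allele
   count equals k (stochastic bisection). The infinite-allele (Ewens)
   estimate is badly too small under stepwise mutation because of homoplasy
   and biases the conditional He|k distribution upward.
2. The two-tailed Wilcoxon signed-rank test across loci is applied to
   *median-centred null percentiles* of the observed diversity within the
   simulated Heq sample. The percentile is exactly Uniform(0,1) under the
   null, hence symmetric about ½ — the symmetry the signed-rank test
   assumes. The conventional standardized excess (He_obs − mean Heq)/sd is
   left-skewed (P(He_obs > mean Heq) ≈ 0.6 under the null) and inflates the
   test several-fold; it is still reported per locus for interpretation.

With this construction the test's measured type-I error is ≈0.03–0.06 at a
nominal α = 0.05. Its power against 100-fold founder crashes at 13 loci and
n = 30 plateaus near 0.5 in the most favourable transient window — a honest
property of a correctly calibrated two-tailed test at this marker count.
Heq distributions are memoised per (k, n, TPM, seed): the null depends on
nothing else, so re-use across loci and populations changes no statistics.

## Synthetic data and what the tests show

The study-template generator produces datasets with the target study's
*shape*: six regional groups (serial samples for PNG and TS/Fly; 30 diploids
per sampling event, 20 for Papua), 13 loci (2 di- + 11 trinucleotide), a
445-bp haploid alignment, and a configurable missing-call rate (3% default),
with a truth ledger of every parameter for recovery tests. It does not
emulate genotyping error, null alleles, allele-binning or dye artefacts
(dye shifts are applied only when testing that correction), selection, or
continuous migration. Passing tests therefore demonstrate the statistical
machinery under the stated model, not robustness to those real-data
artefacts.

Experiment sizes used by the checked-in calibration suite: 2,000 replicates
for the two-tip TMRCA check (tolerance 5%); 200 equilibrium and 200 crash
replicates for the bottleneck operating characteristics; 20,000 reference
rows per scenario and 50 PODs for three-scenario topology recovery; 20,000
rows and 40 PODs for split-time interval coverage. The reproduction script
(`scripts/acceptance.py`) runs the same experiments at roughly half size so
a full run completes in a few minutes on one core.

## Numerical and degenerate-input conventions

Missing genotype calls are pairwise-complete throughout; imputation
(sampled or modal, never across populations) tags calls so
diversity/differentiation statistics can exclude them. Monomorphic loci:
F undefined, M = 1, excluded from the Wilcoxon. Populations with fewer than
4 individuals are reported as insufficient for bottleneck testing; Wilcoxon
requires ≥4 polymorphic loci. Prior order-conditions are satisfied by
rejection resampling with an explicit cap. All stochastic entry points take
explicit seeds; reference-table rows are reproducible per (seed, scenario,
row index).

## Known limitations

* Exact numerical parity with the GUI tools a practitioner might compare
  against (GenAlEx, Arlequin, BOTTLENECK, DIYABC) is not promised; the test
  surface is agreement with the published estimator definitions via
  independent brute-force oracles, plus an external coalescent cross-check.
* The statistical-parsimony network is approximated by a capped minimum
  spanning network.
* No recombination, selection, or continuous migration; admixture is a
  single pulse.
* The logistic CI is asymptotic; for very small retained sets the rejection
  fallback's multinomial CI applies.
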
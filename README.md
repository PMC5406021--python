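# invabc

Invasion-history inference for serially sampled populations: a structured,
serial-sample coalescent simulator with microsatellite (generalized
stepwise) and mtDNA (HKY) mutation models, an approximate Bayesian
computation (ABC) engine for demographic scenario choice and parameter
estimation, and the companion population-genetic statistics used to
characterize spatio-temporal structure — diversity and differentiation with
permutation significance, Garza–Williamson M-ratio and heterozygosity-excess
bottleneck tests, and mtDNA haplotype analysis.

It is written for population geneticists studying biological invasions —
the motivating system is a highly invasive, human-transported mosquito
spreading through an island region, typed at 13 microsatellite loci and a
445-bp mitochondrial *COI* fragment, with serial (multi-year) samples from
recently colonized populations — but every piece (scenarios, priors, locus
panels, sample designs) is configuration.

## The model in brief

A demographic *scenario* is a topology of populations joined by timed
events: splits (introductions), optional admixture pulses, and effective
population-size changes (founder bottlenecks as reduced-Ne epochs of
duration `db`). Genealogies are simulated backward in time under the
Kingman coalescent — with k lineages in a population of size N_e, pairs
coalesce at rate k(k−1)/2 · 1/(ploidy·N_e) per generation — with serial
samples entering as tips at their collection times (10 generations per
year, present = 2015). Microsatellites mutate by a generalized stepwise
model (geometric step sizes, reflecting bound at 2 repeats), sequences by
HKY with exact per-branch transition matrices.

ABC scenario choice is the classic rejection + regression construction:
simulate a reference table under each scenario's priors, retain the closest
simulations to the observed summary-statistic vector (Euclidean distance on
MAD-normalized statistics), fit a multinomial logistic regression of the
scenario label on the centred statistics, and read posterior probabilities
with delta-method 95% CIs at the observed point. Parameter posteriors use
Beaumont local-linear adjustment; confidence in scenario choice (type I/II
error) is measured end-to-end on pseudo-observed datasets; model fit is
checked by PCA projection of the observed vector into the simulated
statistic space. See `docs/methods.md` for the full account.

## Worked example

The `analysis/` scripts run the whole pipeline on a synthetic dataset of
the study's shape (six regional groups, serial samples for two of them, 13
loci + 445-bp mtDNA, 3% missing calls) simulated under shipped scenario 4
with a known, historically plausible truth:

```bash
python analysis/01_simulate_study_data.py
python analysis/02_genetic_diversity.py
python analysis/03_bottleneck_tests.py
python analysis/04_mtdna_diversity.py
python analysis/05_abc_invasion_history.py
```

`01` prints

```
simulated 230 diploid individuals x 13 loci (101 missing calls) and 230 x 445 bp sequences
truth: scenario 4, TSF introduction t2 = 105 generations bp
```

`02` recovers the expected diversity gradient — old SE Asian populations
most diverse, recent founders least — and near-zero differentiation between
serial samples of the same population:

```
  SEA_2015   uHe=0.942  Na=23.31
  ...
  TSF_2015   uHe=0.822  Na=9.46
lowest pairwise F_ST : ('PNG_1992', 'PNG_2011') = 0.000
highest pairwise F_ST: ('TSF_2015', 'SOL_2015') = 0.153
```

`03` flags the founder groups: the Solomons founder (N_e 200) shows both a
depressed M-ratio and significant heterozygosity excess
(`SOL_2015 M=0.44 p=0.000`), while the older, larger populations show at
most one signal. `04` collapses the alignment to 9 haplotypes
(total Hd = 0.616, π = 0.0027) and writes the minimum-spanning haplotype
network. `05` rebuilds a reference table over all five invasion scenarios
(400 simulations per scenario by default) and runs scenario choice and
parameter estimation against the known truth:

```
true scenario: 4; chosen: 4 (logistic)
  scenario 1: P=0.176 [0.045, 0.308]
  scenario 4: P=0.514 [0.351, 0.678]
  scenario 5: P=0.309 [0.164, 0.455]
  t2: ~2004 [95% CI 2002, 2006] (truth 2004)   # Torres Strait/Fly introduction
  t3: ~1980 [95% CI 1974, 1985] (truth 1979)   # Solomons
  t4: ~1970 [95% CI 1959, 1979] (truth 1970)   # PNG
  t5: ~1958 [95% CI 1943, 1966] (truth 1959)   # Papua
```

The generating scenario wins the posterior and every introduction-time
95% interval covers its true calendar year. All outputs land in
`results/study_like/`.

## Command-line pipeline

For real data the same stages run from one JSON config:

```bash
invabc qc config.json        # dye-shift, >=9-of-13 locus filter, imputation
invabc stats config.json     # diversity + pairwise FST/G''ST/Jost's D (+ permutations)
invabc bottleneck config.json
invabc mtdna config.json
invabc abc config.json       # reference table, scenario choice, estimation, model check
invabc all config.json
```

The config carries input paths (genotype CSV with two columns per locus;
FASTA with `id|population|year` headers), the locus panel, scenario files,
seeds, simulation counts, tolerance and the output directory; outputs are
never overwritten without `--overwrite`.

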
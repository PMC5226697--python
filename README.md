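# mutamosaic

Mutation burden and mosaicism from pooled-plaque *lacZ* transgene sequencing.

Transgenic-rodent (Muta™Mouse) mutation assays recover a bacterial *lacZ*
reporter from tissue DNA, select mutant phage plaques in *E. coli*, and report
a **mutant frequency** (MF = mutant plaques / total plaques, displayed
×10⁻⁵) per animal and tissue. Sequencing a pool of the mutant plaques as one
amplicon library (in duplicate) additionally reveals *which* mutations are
present and *how many plaques* carry each one — so clonally expanded
mutations, the footprint of somatic and germline mosaicism, can be separated
from independent singletons.

`mutamosaic` implements that computational chain for toxicologists and
genetic-toxicology bioinformaticians:

* **`pileup`** — parse `samtools mpileup` text into per-position base-count
  matrices over the *lacZ* reference and compute per-position alternate-allele
  proportions.
* **`calling`** — call unique mutations in a pool: a (position, alternate)
  event must exceed the pooled calling threshold `1 / n_plaques` in **both**
  technical-replicate libraries, and its background rate (median proportion
  across all libraries of the experiment) must be **< 2 %**.
* **`clonality`** — convert mean proportions to plaque counts
  (`raw = p̄ × n_plaques`), apply a limit-of-detection / linear calibration
  (raw counts below the LOD collapse to singletons), and summarise the
  proportion of clonally expanded mutations per tissue/dose — the working
  proxy for mosaicism.
* **`spectra`** — classify mutations into purine-reference categories
  (G→T, G→C, G→A, A→T, A→G, A→C, INS, DEL) and compare spectra between groups
  with exact conditional tests (full hypergeometric enumeration for 2×2,
  seeded Monte-Carlo for larger tables) with Bonferroni correction.
* **`mfstats`** — the dose-response model, statsmodels-style. For counts
  *y<sub>i</sub>* with totals *T<sub>i</sub>*:

      y_i ~ quasiPoisson(mu_i),   log mu_i = x_i' beta + log T_i

  fitted by IRLS with dose as a factor; dispersion φ = Pearson X²/(n−p);
  per-dose fold changes exp(β_d) with Wald *t* intervals on n−p df and
  Bonferroni-corrected p-values. A Poisson-rate homogeneity LRT screens
  discordant technical replicates within animals, then animals within dose
  groups (opt-in, fully logged). `MutantFrequencyModel(data).fit()` returns a
  `DoseResponseResults` with `params`, `bse`, `fold_changes()`, `summary()`.
* **`simulate`** — a ground-truthed generator for every stage: gamma-mixed
  Poisson per-animal plaque counts at doses {0, 10, 20, 40} mg/kg/day, plaque
  pools with zero-truncated-geometric clone sizes, condition-specific spectrum
  weights, duplicate libraries with per-base error and injectable systematic
  artifact sites.
* **`exposure`** — exact dose-context arithmetic (cumulative dose, per-kg
  dietary dose, allometric interspecies scaling with the ¾-power default).
* **`mutamosaic`** CLI — `simulate`, `call`, `clonality`, `spectrum`, `mf`,
  `dose-metrics`, `all`; every output directory gets a `manifest.json` with
  seeds, thresholds and input checksums.

## Worked example

Simulate a cohort (5 animals/dose, baseline MF 5×10⁻⁵, over-dispersed between
animals) and fit the dose response:

```python
from mutamosaic.simulate import SimConfig, simulate_cohort
from mutamosaic.mfstats import MutantFrequencyModel

records, truth = simulate_cohort(SimConfig(seed=42))
print(MutantFrequencyModel(records).fit().summary())
```

```
Quasi-Poisson dose-response GLM (log link, offset log total plaques)
  observations: 20   dose coding: factor
  dispersion (Pearson X2/df): 5.3639   df_resid: 16   IRLS iterations: 5

  term              coef        se        t          p
  Intercept      -9.7323    0.2455  -39.643    2.1e-17
  dose[10]        1.0720    0.2844    3.769    0.00168
  dose[20]        1.9539    0.2623    7.449   1.38e-06
  dose[40]        2.4141    0.2562    9.421   6.26e-08

    dose     fold              95% CI          p     p_bonf
      10     2.92        [1.60, 5.34]    0.00168    0.00504
      20     7.06       [4.05, 12.30]   1.38e-06   4.15e-06
      40    11.18       [6.49, 19.25]   6.26e-08   1.88e-07
```

The generating fold changes for this seed were {3, 8, 16}: the top-dose
estimate 11.18 [6.49, 19.25] reflects ordinary sampling error of a 5-animal
group under between-animal over-dispersion (φ ≈ 5.4); the Bonferroni column
multiplies each p-value by the three non-control contrasts.

The end-to-end pipeline on files:

```sh
mutamosaic simulate --seed 7 --config small.yaml --out run/
mutamosaic all --sim-dir run/ --out analysis/     # calls, clonality, spectra,
                                                  # MF fit + recovery report
mutamosaic dose-metrics                           # dose-context JSON
```

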
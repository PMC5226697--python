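# Methods

This note documents the models and procedures implemented in `mutamosaic`,
the default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices and known
limitations a user should be aware of.

## The assay and its observables

A transgenic-rodent *lacZ* assay yields, per animal and tissue, a mutant
plaque count and a total plaque count; the mutant frequency (MF) is their
ratio. Mutant plaques pooled from one animal/tissue are PCR-amplified and
sequenced as one amplicon library in **duplicate technical replicates**.
Because every plaque in the pool is a mutant, a genuine mutation carried by
at least one whole plaque must occupy at least `1/n_plaques` of the reads —
the *pooled calling threshold*. Reading depth per position is high
(~20,000×), so the read proportion of a mutation estimates the fraction of
plaques carrying it.

## Pileup decoding

Input is `samtools mpileup` 6-column text against the plus-strand *lacZ*
reference (1-based). `.`/`,` count toward the reference base; base letters
count toward their alternate with strand case collapsed (the assay carries no
strand information at the plaque level); `+n<seq>`/`-n<seq>` increment an
insertion/deletion event anchored at the preceding base and keyed by its
sequence, so indel identity includes length and content; `^` (with its
mapping-quality byte), `$` are consumed without counting; `*` and `N`
contribute to depth only — the deletion event was already counted at its
anchor. Base and mapping qualities are ignored: the caller's replicate
intersection and background filter are the error controls. Positions absent
from the file are zero-depth (as `mpileup` without `-a` emits); out-of-order
or out-of-range positions and reference mismatches are hard errors naming the
line. The depth column must equal the number of decoded reads.

## Mutation calling

A candidate (position, alternate) is called when its proportion strictly
exceeds `1/n_plaques` in *both* replicate libraries and its background rate
is `< 2 %` (configurable). The background rate of an aggregate event class
(A/C/G/T/INS/DEL) at a position is the **median** of its proportion across
*all* libraries of the experiment. The median was chosen because a
systematic platform artifact recurs in every library (median ≈ its rate)
while a genuine clonal mutation is private to one pool (median ≈ the error
rate); the sample being called is not excluded, since with six or more
libraries its own contribution cannot move the median past the cutoff.
Whether the original analysis computed background from control libraries only
is not documented; both variants are expressible through the `libraries`
argument.

Consequences worth knowing:

* a singleton mutation sits *exactly at* the threshold (`1/n_plaques`), so
  under read noise roughly half of true singletons fail the strict comparison
  in a given library; clones of two or more plaques are comfortably above it.
  The caller's high-recall guarantees are therefore stated for mutations with
  proportion ≥ `2/n_plaques`.
* calls grow monotonically when the pool size rises (threshold falls) or the
  background cutoff rises; the test suite enforces both.

## Clonality correction and mosaicism

`raw = mean proportion × n_plaques` estimates the plaque count of a
mutation. Raw counts near one are unstable, so a **limit-of-detection /
linear** correction maps them to integers: below `lod_count` the corrected
count is 1 (singleton); above it, `round(intercept + slope × raw)` (half away
from zero) floored at 1. The parameters of the original correction live in
prior work and are not restated, so the package ships (a) a calibration
fitter — OLS of true on observed counts, with the LOD defined as the smallest
observed raw count whose observation prediction-interval lower bound exceeds
1 on the calibration data — and (b) a default identity calibration with
`lod_count = 2`, preserving the qualitative contract (small counts collapse
to singletons, larger counts scale linearly). A mutation with corrected
count > 1 is *clonally expanded*; the proportion of expanded mutations per
tissue/dose group is the mosaicism proxy. Two independent plaques carrying
the same mutation in one tissue are deliberately merged into one clonal event
— the conservative within-tissue assumption — and a test documents this
merging as designed behaviour, not a bug.

Boundary behaviour: a size-2 clone's raw count is centred exactly on the
default LOD of 2, so under binomial read noise about half of size-2 clones
land below it and are reported as singletons. Clonal-fraction recovery is
therefore demonstrated in the simulator's deterministic-read mode, which
isolates the correction logic; with noisy reads the estimated clonal fraction
is biased low by this boundary effect, in proportion to the share of size-2
clones.

## Mutation spectra

Substitutions are reported with a purine reference (C→A ≡ G→T after
complementing), giving six substitution categories plus INS and DEL. Spectra
default to counting unique mutations once; corrected-count weighting is
available as a sensitivity analysis. Between-group comparisons condition on
the margins of the category-by-group table: a table that collapses to 2×2 is
tested by full hypergeometric enumeration (two-sided by the
probability-ordering rule, with the relative tolerance 1e-7 customary for
such tests); larger tables use a seeded Monte-Carlo exact test (≥ 10⁵ tables
drawn by multivariate hypergeometric sampling with fixed margins). The seed
and resample count are recorded in the comparison output. Bonferroni
correction multiplies by the number of comparisons performed. Whether all
eight categories or substitutions only enter the test is exposed as
`substitutions_only` (default: all categories).

## Dose-response model

Mutant counts are modelled as quasi-Poisson with log link and offset
`log(total plaques)`, dose coded as a factor (default; a continuous trend
coding is available). The IRLS implementation converges when
`max |Δβ| < 1e-8` (at most 100 iterations); with the canonical link and
factor coding the fitted group totals equal the observed group totals
exactly, which serves as the implementation oracle, and the fit is
cross-checked against an independent GLM implementation in the tests.
Dispersion is φ = Pearson X²/(n−p); standard errors are Poisson standard
errors × √φ; inference uses Wald *t* on n−p degrees of freedom (standard
quasi-likelihood practice); per-dose fold changes are exp(β_d) with *t*
intervals, Bonferroni-corrected over the non-control contrasts (three in the
default design). A dose level with all-zero mutants leaves its coefficient
diverging to −∞ while the fitted means converge; the fit warns, accepts on a
stable deviance once a fitted mean has collapsed to zero, and reports the
(unstable) estimate rather than failing.

### Coverage of dispersion-scaled Wald intervals

The generator draws per-animal MF from a Gamma with fixed shape, so the count
variance is μ + μ²/shape (NB2-like), while quasi-Poisson assumes a common
φ·μ. With large fold changes φ is dominated by the high-mean dose groups,
yet the variance of a log fold-change contrast is dominated by the
control group's 1/Σμ₀ term, which does not warrant that inflation. The
intervals for large folds therefore **over-cover**: measured across seeds
1–200 at n = 5/group, coverage is ≈ 0.96 at fold 3 but ≈ 0.99 at folds 16–33.
This is a structural property of pairing a single-dispersion quasi-likelihood
with gamma-mixed counts — conservative, not anti-conservative — and is
reported as measured. Fold-change *recovery* is unbiased on the log scale
(geometric-mean error < 1 % across 200 replicates); the arithmetic mean of
exp(β̂) carries the usual ratio-estimator Jensen bias ≈ CV² of the control
group total (~5 % under the default conditions), which is why recovery is
stated geometrically.

## LRT outlier screen

Homogeneity of Poisson rates across k units sharing offsets is tested with
G = 2 Σ yᵢ log(yᵢ/ŷᵢ), ŷᵢ = totalᵢ × (Σy/Σtotal), against χ²(k−1) (zero
counts contribute nothing). While the test rejects at α (default 0.05), the
unit with the largest absolute deviance residual is removed — note this is
often the *low* count of a discordant pair, since low counts deviate further
in deviance terms — and the screen stops when the test accepts or fewer than
two units remain. It runs first across technical replicates within animals,
then across animals within dose groups; it is opt-in and every statistic and
removal is returned in a trace — data are never silently deleted. The G test
is asymptotic and mildly liberal at moderate counts (true type-I ≈ 0.052 at
mean count 20 with k = 4, reaching 0.050 by mean ≈ 100), so the realised
false-removal rate on homogeneous groups at control-like counts sits slightly
above α; this is a property of the asymptotic reference distribution, not of
the implementation.

## Synthetic-data generator

What it emulates: the four-dose design (0/10/20/40 mg/kg/day), gamma-mixed
Poisson per-animal mutant counts, pools of `n_plaques_pooled` mutant plaques
whose unique mutations have clone sizes 1 or 2 + Geometric(p) (zero-truncated;
sizes are drawn until they fill the pool exactly, and a clonal draw that
cannot fit in a single remaining plaque extends the previous clone rather
than degrading to a spurious singleton), condition-specific spectrum weights
(a G→T-dominant adduct-like signature for exposed pools, a
transition/deletion-rich spontaneous background for controls — qualitative
mimics, not published numbers), category-consistent placement at distinct
reference positions, duplicate libraries with per-base miscall error spread
over the three non-reference bases, and declared position-specific systematic
artifacts injected into *every* library (true mutations avoid declared
artifact positions, where they would be unidentifiable by design).

What it does not emulate: read-level errors and alignment, PCR cycling and
jackpot effects, homopolymer-dependent indel error (the `artifact_sites` hook
can mimic specific sites), coverage variation along the amplicon, or
contamination between pools. Passing recovery tests therefore demonstrate the
correctness of the statistical chain under its stated assumptions, not
robustness to every artefact of a real sequencing run.

Defaults (chosen as realistic for this assay and fixed): 5 animals/dose;
baseline MF 5×10⁻⁵; fold-per-dose {0: 1, 10: 3, 20: 8, 40: 16} (a
bone-marrow-like response); gamma shape 10 for animal-level MF (between-animal
CV ≈ 32 %); 300,000 total plaques/animal (so ~15 control mutants); 100 plaques
pooled; clonal fraction 0.4 with geometric parameter 0.5 (mean clone size
3); coverage 20,000×; error rate 0.1 %. `count_sampling="expected"` replaces
binomial read draws with rounded expectations for exactness checks. All
randomness flows from one integer seed through numpy `SeedSequence` streams;
a fixed seed reproduces byte-identical outputs.

## Recovery experiments and problem sizes

The acceptance battery (and `scripts/acceptance.py`) uses desk-scale problem
sizes chosen by the package: 200 seeded replicate cohorts per generating fold
(two groups of 5 animals; folds 3, 16, 18 and 33 — the magnitudes of the
sperm, bone-marrow, brain and liver effects the design targets), caller
scoring on 8 pools of 60 clonally expanded mutations at 20,000× with a 4 %
artifact, clonal-fraction recovery on four pools of ~220 unique mutations,
a ~220-table stride sweep of 2×2 margins (N ≤ 30) for Monte-Carlo/enumeration
agreement, and 1,000 homogeneous groups for the screen's false-removal rate.

## Exposure arithmetic

`cumulative_dose` is the product of daily dose and days (0.68 mg/kg-bw/day ×
10 days = 6.8 mg/kg-bw; 0.8 × 730 = 584). `per_kg_dose` divides a whole-body
daily intake by body weight (17 µg/day at 60 kg → 0.28 µg/kg/day at the
2-decimal display convention). `allometric_scale` scales a per-kg dose
between body masses by (w_from/w_to)^(1−exponent) — three-quarter-power
metabolic scaling of total dose, the default exponent 0.75 reproducing the
0.28 → 1.9 µg/kg/day human-to-mouse conversion; the exponent is exposed
because interspecies-correction conventions differ.

## Known limitations

* Independent recurrent mutation cannot be distinguished from clonal
  expansion within one pool; the corrected count deliberately merges them.
* Base/mapping qualities are ignored; quality-aware filtering is out of
  scope.
* The identity/LOD default calibration is a stand-in for an
  experiment-specific calibration; supply measured calibration data where
  available.
* Benchmark-dose model fitting and averaging are out of scope; only the dose
  arithmetic around such analyses is provided.
* Emitted pileup text scales as coverage × reference length × libraries;
  full-depth bundles are large, so file-based workflows should use the
  desk-scale configurations (the in-memory API has no such constraint).
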
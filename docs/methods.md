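# Methods

This note records the models implemented in `seasonscan`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Pool-seq sampling model

A pooled sample of `N_chr` chromosomes sequenced to depth `N_rd` yields an
allele-frequency estimate with two binomial noise layers: chromosomes into
the pool, reads from the pool. The marginal variance is
`f(1-f)(1/N_chr + 1/N_rd - 1/(N_chr N_rd))`, which the package summarises
by the harmonic effective size `n_eff = N_chr N_rd/(N_chr + N_rd)`
(`fst.effective_n`). `n_eff` is used both as the GLM prior weight and in
the FST correction. The difference between `1/n_eff` and the exact
variance is the cross term `1/(N_chr N_rd)` — negligible at the depths and
pool sizes modelled here.

Pools are male flies, hemizygous on the X: `SampleMeta` stores an
autosomal chromosome count and an X count defaulting to half of it. All
statistics take the per-chromosome count through
`SampleMeta.chromosomes(chrom)`.

## Corrected FST

Per SNP, `FST = (H_T - H_W)/H_T`. Within-sample heterozygosity is
unbiased for binomial sampling of `n_eff` chromosomes:
`h_i = 2 p_i q_i n_i/(n_i - 1)`. For the total heterozygosity the relevant
sampling unit is the mean of the two estimated frequencies, whose variance
under panmixia is `pq/(2 ñ)` with `ñ` the harmonic mean of the two
`n_eff`; its unbiasing factor is therefore `2ñ/(2ñ - 1)`. This combination
centres the estimator at zero under the double-binomial null (verified to
within Monte-Carlo error at 1e5 replicates) and makes negative estimates
routine — they are never clipped, and sites fixed in both samples are NaN
and excluded from means. The algebra is isolated in `fst.snp_fst`.

The permutation null redraws both samples double-binomially around the
pair's mean frequency with each sample's own `N_chr` and depth.
`proportion_exceeding` compares observed per-SNP FST with a per-SNP null
quantile (default the 95th percentile; the exact summary the original
analysis used is not stated, so it is configurable). Note the finite-
permutation bias of an estimated quantile: with `n` permutations the null
exceedance probability of the 95th-percentile rule is about
`(0.05 n + 1)/(n + 1)`, so ~400+ permutations are needed for the null rate
to sit near 0.05.

### Block "bootstrap"

Resampling draws one SNP uniformly per occupied 50-kb genome-anchored
window (windows start at position 0 per chromosome). This is an
LD-thinning resampler, not a classical bootstrap: with at most one SNP per
window the draw is deterministic and the spread collapses. Its intervals
are therefore meaningful when focal SNPs are denser than one per window,
and understate uncertainty otherwise; the dense-genome configurations in
the test suite exist for exactly this reason.

## Seasonal and clinal scans

Per SNP, a binomial-logit GLM of sample allele frequency on a spring/fall
indicator (Pennsylvania series) or on latitude (clinal samples only),
with prior weight `n_eff` per observation. The solver is an IRLS
vectorised across SNPs (two-parameter normal equations solved in closed
form per SNP); it matches `statsmodels` GLM with `var_weights` to 5+
significant digits, and `statsmodels` serves as the independent oracle in
the tests. p-values are Wald z tests on the predictor; non-convergence
within 50 iterations or |coefficient| > 30 (separation) flags the record
and propagates NaN. BH q-values come from
`statsmodels.stats.multitest.multipletests` with NaN propagation.

The cumulative selection coefficient is
`S = |logit f_fall - logit f_spring|`: under logistic allele-frequency
dynamics a per-generation coefficient `s` acting for `t` generations with
dominance weight `h` displaces the logit by `s h t`, so `s = S/(h t)` with
`h` and `t` supplied by the caller. `S` is reported per SNP from the
spring/fall mean frequencies of that SNP; a mean-level variant (means over
the seasonal set first) is a one-liner on the scan output, and the per-SNP
form is what the power machinery conditions on.

Power is Monte Carlo: SNPs oscillating ±S/2 on the logit scale around a
uniform base frequency, sampled double-binomially under the design
(3 spring + 3 fall pools, 100 chromosomes, negative-binomial depth with
mean 80), scanned by the same GLM; power = fraction with p < alpha. The
alpha corresponding to a q-value threshold is dataset-specific, so
`alpha_for_q` extracts it from a given scan rather than hard-coding it.
`expected_total` inflates observed counts by 1/power per S bin.

## Matched-control enrichment

Control SNPs are matched exactly on discretised covariates; the defaults
round frequency to 0.05 and recombination rate to 1 cM/Mb (the original
matching tables are not public; both grids are arguments). Focal SNPs
with an empty stratum are dropped and reported. The statistic grid is
(500 control sets) x (500 block-thinned focal subsets); a 2x2 table per
cell gives a log2 odds ratio with the Haldane–Anscombe 0.5 correction on
zero cells; E and SD are the grid mean and SD, the CI the 2.5/97.5
percentiles, and the two-sided p the sign-reversal tail probability of
the grid. These intervals carry focal-side sampling noise only when
focal SNPs are dense relative to the 50-kb windows (see above).

The frost test defines overshoot as a strict directional crossing:
`sign(longterm - post) != sign(longterm - pre)`, with SNPs at
`pre == longterm` excluded. Controls are additionally matched on the
rounded |pre-frost - long-term| displacement. The synthetic experiments
show exactly why: selecting focal SNPs with large *observed* displacement
on null data produces a strong spurious deficit of overshoot without the
displacement match and a calibrated zero with it. One caveat the
synthetic world makes visible: when focal SNPs have *true* displacement
(planted oscillators with no frost effect) while the pool's displacement
is pure noise, matching on observed displacement cannot equalise the two
groups — the matched null is exact only when focal and pool displacement
structures are exchangeable. The generator gives neutral SNPs no
inter-annual drift, which makes this sharper in tests than it would be in
real data, where control displacements are partly real.

The overdispersion test counts seasonal SNPs per 1000 consecutive SNPs
(windows never span chromosomes; a trailing partial window is dropped),
fits a Poisson GLM on chromosome type (autosome/X) and mean recombination
rate, reports Pearson chi^2/df as the dispersion ratio, and tests
Var = (1+a)mu one-sided via the Cameron–Trivedi auxiliary regression of
`((y-mu)^2 - y)/mu` on a constant. On counts planted with
Var = 2.3 x mean, the ratio recovers ~2.3 and the test rejects.

## Boom-bust forward simulator

Diploid Wright–Fisher, one chromosome (default 20 Mb at 2 cM/Mb, i.e. 0.4
Morgans), random mating with selfing allowed. Fitness is genic and
multiplicative on the log scale: `w = exp(s_season x winter-allele
copies)`, so an infinite population shifts allele frequency by exactly
`s_season` logit units per generation. `calibrate_selection` therefore has
the closed form `s_summer = +Delta/10`, `s_winter = -Delta/2` with
`Delta = logit(0.6) - logit(0.4) = 0.811` — per-generation coefficients of
8.1% (summer) and 40.5% (winter) for the default 0.40<->0.60 oscillation.
A `deterministic` mode propagates the logistic recursion directly and is
tested for exact agreement.

Each 12-generation cycle is 2 winter generations at the overwintering
size `n_min` (the first reproduction is the crash) followed by 10 summer
generations growing exponentially to `n_max = 1e5`. The run length is 96
generations (8 complete cycles) so that the "last three cycles" are well
defined; gametes get Poisson crossovers on a uniform genetic map. Neutral
loci (500, uniform positions) start at 0.5 in linkage equilibrium;
selected loci (equidistant) start at the fall peak 0.6 since the run
opens at the start of winter.

Sampling conventions, chosen once: the *fall* sample is the last summer
generation (the peak); the *spring* sample is the first generation of
expansion — one summer generation after the trough, as a field collection
early in the growing season would be; the *trough* (end of winter) is
recorded too, and the reported oscillation amplitude is peak-to-trough,
which equals the designed 0.20 in expectation. Samples are pseudo-pools
(100 chromosomes, 100x depth, double-binomial) so simulated FST is
directly comparable to the data pipeline; mean neutral FST averages the
corrected estimator over defined neutral loci and the three within-cycle
spring-fall pairs of the last three cycles. Cross-winter pairs would be
dominated by the crash itself (~1/n_min) and are not part of the summary.

Under pure drift this construction gives mean FST close to the analytic
`(1/4) sum_t 1/(2 N_t)` over the between-sample generations: about 0.002
at an overwintering size of 10-20 and an order of magnitude less at 200,
where adding ~10 selected loci restores data-scale FST through genetic
draft — the qualitative contrast the simulator exists to show. Runtime is
~10-15 s per full-scale replicate on one CPU; the test suite uses
`n_max = 1e4` and fewer loci, which preserves every ordering but shifts
drift magnitudes upward slightly (smaller summer populations).

## Recolonisation and truncation models

The recolonisation model is exact: founder counts are
`k ~ Binomial(2 n_founders, f)`; a SNP "cycles" if the founder frequency
deviates from the refugium frequency by at least the threshold (default
0.20, the mean seasonal amplitude) in the same direction in each of 3
years; the per-direction probabilities are binomial tail sums and the
expected count is summed over SNPs. The exact detection rule behind the
original figure is unstated, so the implementation makes no claim to
reproduce its absolute counts — the object of interest is the ~2x
collapse of the expectation per added founder, which is rule-robust.

Truncation selection: with `m` independently segregating loci, the
winter-allele count per diploid is approximately Poisson with mean
`2 sum f`. The surviving fraction over winter is
`P(X >= ceil(2 sum f_spring))` for `X ~ Poisson(2 sum f_fall)` and the
minimum census is its reciprocal, resampled over loci when an observed
scan supplies the frequency pairs. Two rounds split the logit shift
evenly and multiply the two tails. The integer ceiling makes the census
non-monotone below ~5 loci and can make two rounds *costlier* than one at
small locus counts; both discreteness artefacts disappear by ~50 loci.

The bottleneck SFS module evolves an SFS-shaped (density ~ 1/f) spectrum
through 1-2 generations of binomial sampling at the bottleneck size and
pseudo-pool samples both states, excluding sampled frequencies within
2/depth of fixation (sequencing-error guard). A crash to ~20 individuals
visibly depletes the rare bins — the signature whose absence in real
spring samples argues against severe winter bottlenecks.

## Synthetic-data generator

The generator emulates the study conditions: 6 Pennsylvania spring/fall
pools (2009-2011) plus 5 clinal pools at 25.5-44.8° latitude, 100 pooled
chromosomes each, negative-binomial depths (mean 80, shape 10, spanning
roughly 20-200x), base frequencies uniform on [0.15, 0.85]. Seasonal
SNPs oscillate ±0.10 around their base on the natural frequency scale
(point-mass amplitude 0.20 — the real amplitude distribution is not
tabulated); clinal SNPs follow a logit-linear latitude trend centred at
40° with N(0, 0.05 /degree) slopes; a post-frost sample sits `gamma` of
the way back from fall towards spring. Synthetic GWAS directions agree
with the winter-favoured allele's predicted phenotype direction with
probability `pi` at seasonal SNPs and are coin flips elsewhere.

What the generator does *not* model: linkage between SNPs (sites are
independent; linkage lives in the forward simulator), inter-annual drift
of the truth, library/mapping artefacts, and overlapping generations.
Passing tests therefore certify the statistical machinery under its own
sampling assumptions — calibration on real data additionally depends on
LD structure and demographic heteroscedasticity that the GLM scan is
known not to capture fully.

## Numerical choices

IRLS: initialisation from shrunk observed frequencies, convergence at
1e-8 on the coefficients, 50-iteration cap, separation flag at
|coef| > 30, mu clipped to [1e-10, 1-1e-10]. Odds ratios: 0.5 added to
all four cells when any is zero. Poisson/binomial tails: exact scipy
summation; truncation tails reported as a >1e15 sentinel on underflow.
Block windows are fixed and genome-anchored so block assignment is
deterministic. All randomness flows through `numpy.random.Generator`
seeds carried in configs; identical seeds give byte-identical outputs.
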
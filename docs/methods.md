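# Methods

## The model

Each sister-species pair is a two-deme isolation(-with-migration) model:
two demes of constant diploid effective size N split from a panmictic
ancestral deme (also size N) T generations ago, with T/N in {2, 4, ..., 16}
across the eight pairs.  Ten haploid sequences are sampled per species.
Gene flow, when present, is confined to one epoch of length 2N generations:

* **early** — the epoch [T − 2N, T) immediately after the split
  (divergence with gene flow, then complete isolation);
* **recent** — the epoch [0, 2N) before the present (secondary contact).

For the youngest pair (T = 2N) the two placements coincide.  The scaled
migration parameter 4Nm sets the per-generation lineage migration rate
m = 4Nm/(4N).  "Unidirectional" gene flow means backward-in-time lineage
movement from species 2 into species 1 — equivalently, forward-in-time
migrants from species 1 into species 2; this convention is fixed here
because nothing in the two-deme model distinguishes the directions
otherwise.  Sister pairs are simulated independently: under neutrality with
gene flow only between sisters, non-sister history cannot affect
within-pair genealogies, and all statistics are computed within pairs.

Default nominal parameters: N = 10^6, sequence length 100 kbp, mutation
rate mu = 5e-9 and recombination rate rec = 1e-8 per site per generation,
giving 4Nmu = 0.02 and 4Nrec = 0.04 per site.  30 replicates per scenario.

**Desk scaling.**  All statistics computed here depend on the parameters
only through 4Nmu, 4Nrec, T/N, 4Nm (and, with selection, 2Ns, m/s and
rec·d/s), so a c-fold rescaling (N/c, rates ×c, selection coefficients ×c,
ages fixed in units of N) leaves every result invariant in distribution.
Experiments default to c = 100 (N = 10^4); the scale-invariance is itself a
test (Kolmogorov–Smirnov on fitted-coefficient distributions at c = 100 vs
c = 200).

## Engines

* **Neutral recombining ancestries** come from msprime's exact
  coalescent-with-recombination (Hudson) engine, wrapped behind this
  package's demography builder.  The exact model is preferred over the SMC'
  approximation because the engine makes it no more expensive.
* **JC69 mutation** is finite-sites: uniform root base, Poisson
  substitutions at rate mu per site per generation along each branch,
  uniform choice among the three alternative bases, multiple hits allowed.
  Two implementations exist — this package's own, operating on explicit
  per-interval genealogies, and msprime's C mutation generator for the
  neutral fast path — both validated against the JC69 closed form
  p = (3/4)(1 − e^{−4·mu·t/3}).
* **Selection** uses this package's own backward structured coalescent
  (below).  With all selection coefficients zero it reduces to a
  single-locus two-deme coalescent that doubles as an independent
  cross-check of the msprime path (two-sample KS tests in the suite).

## The selection model

A single biallelic locus adjacent to the neutral region carries
mirror-image semidominant divergent selection: genotype fitnesses
(1 + s_hom, 1 + s_het, 1 + s_other) for the locally favored homozygote,
heterozygote and other homozygote, defaults (0.01, 0.005, 0), with the
favored allele swapped between demes.  The demes are taken to be fixed for
alternative alleles at the split (divergence from a standing difference).

At these parameters selection at the locus is overwhelmingly strong
relative to drift and migration (2N·s_het = 10^4; m/s_het ≤ 10^-3 for
4Nm ≤ 10), so the allele frequencies sit at the deterministic
migration–selection balance: the receiving deme carries the immigrant
allele at q* = m/s_het.  The linked neutral region is simulated backward
under the structured coalescent conditioned on those frequencies: each
lineage carries a (deme, allelic background) state; recombination at rate
rec·d (d = distance to the locus) moves it between backgrounds with
probability proportional to the background frequencies; backward migration
is weighted by the frequency of the lineage's background among migrants.
The model's effective neutral gene flow at distance d is analytically
m_e = m·rec·d/(rec·d + s_het) — Bengtsson's classical gene-flow factor —
which is how the selected locus acts as a barrier whose strength decays
with distance.  At the end of a recent-contact epoch (backward in time) the
immigrant background collapses (q → 0 at rate s_het); lineages stranded on
it resolve by exact inversion sampling of the competing recombination,
coalescence and trace-to-migrant hazards.  The engine refuses parameters
outside the strong-selection regime (2N·s_het < 50 or q* > 0.2) instead of
extrapolating silently.

A forward Wright–Fisher frequency simulator (two demes, selection,
epoch-limited migration, binomial drift) is provided for trajectory
analysis and is validated against Kimura's diffusion fixation probability;
it refuses rescalings that would push a fitness coefficient above 1 (at the
nominal parameters 2Ns cannot be preserved at a desk-scale population size
in a discrete WF scheme — that regime is exactly the deterministic limit
the coalescent engine handles).

**Resolution.**  Each 500-bp window of the selection pipeline is simulated
as one non-recombining locus at its midpoint distance from the selected
site.  Linkage of each window to the locus is modeled; recombination
within windows and genealogical correlation between windows are not.  Mean
window statistics and their distance profile are unaffected; the
window-to-window correlation that the bridging rule exploits is
understated, so only directional claims (F_ST gradient, ΔAIC signs,
plateau vs growth) rest on this engine.

## Scan and outlier statistics

Hudson's F_ST per window is the ratio of sums over the window's polymorphic
sites: F_ST = 1 − ΣH_w / ΣH_b, with per-site H_w the average of the two
within-species mean pairwise differences and H_b the between-species mean
pairwise difference.  Ratio-of-sums is the standard recommendation for
multi-site Hudson estimates; mean-of-per-site-ratios is noticeably noisier
in low-polymorphism windows.  Windows with ΣH_b = 0 are undefined (NaN):
they are excluded from pooled thresholds, can never be outliers, and break
bridges.  Negative F_ST values are retained.  d_xy is the mean between-
species per-site difference over all sites of the window; fixed differences
are sites monomorphic within each species for different bases.

Outlier thresholds are empirical percentiles (75/80/95/99, linear
interpolation of order statistics — numpy's default, R type 7) of the
per-window F_ST pooled across **all eight pairs** of one replicate.  A
single absolute threshold across pairs is essential: per-pair thresholds
would remove precisely the divergence-time signal under study.  An outlier
is a window with F_ST strictly above the threshold (ties are not outliers).
The default "relaxed" rule flags windows above the 95th percentile and then
promotes every maximal run between two flagged windows of the same pair iff
all its windows have defined F_ST above the 75th percentile; bridges never
cross pair boundaries or extend past a pair's outermost flagged windows.

## Growth curves and model choice

Per replicate, the (x, y) series of x = T/N in {2..16} and y = outlier
window count is fit by least squares with y = c·x (closed form) and
y = a(1 − e^{bx}) (a profiled analytically given b — a(b) = Σyu/Σu²,
u = 1 − e^{bx} — with a sign-spanning log-spaced grid of b in
±[0.01, 1.5] followed by bounded refinement, tolerance 1e-10, iteration cap
1000).  The scale of b depends on the x units; x is always divergence time
in units of N generations here.  Series whose least-squares profile has no
interior optimum (counts flat in age, as under strong recent gene flow)
are reported as nonconverged — the analogue of iteration-capped divergence
of unconstrained Gauss–Newton on such data; the fitter was validated
against R's `nls` on reference series (agreement to 4 decimal places).
b < 0 (with a > 0) is the saturating "plateau" branch.  AIC uses the
Gaussian likelihood with unknown variance, AIC = n·ln(RSS/n) + 2k with
k = 2 (linear) and 3 (exponential); RSS = 0 maps to a −inf sentinel.
ΔAIC = AIC_lin − AIC_exp, positive when the exponential wins.

Scenario comparison: one-way fixed-effects ANOVA on the converged b values
(scenarios with majority nonconvergence are excluded, with counts logged),
Tukey HSD with compact significance letters (maximal cliques of the
non-significant-pair graph), and bias-corrected-and-accelerated bootstrap
CIs of the mean b (jackknife acceleration; a BC-only flag is provided since
"bias-corrected bootstrap" is sometimes meant without acceleration;
degenerate constant input yields a zero-width interval).

## Problem sizes

Replication runs use c = 100 with a reduced region: 80 kbp in
`scripts/acceptance.py`, 50 kbp in the heavy acceptance tests, 10 kbp in
the scale-invariance KS test.  The coefficient b is insensitive to region
length in expectation (halving the region halves the counts, which the
amplitude a absorbs); shorter regions mainly add count noise, which
inflates the replicate SD of b and can bias its mean slightly upward, so
the largest region that keeps a full three-scenario replication within a
desktop time budget is used.  Measured on the no-gene-flow scenario, mean
b moves from ≈0.44 (100 kbp) to ≈0.46-0.47 (50 kbp) with replicate SD
growing from ≈0.07 to ≈0.15.

## What the generator does and does not emulate

The simulator *is* the study's data generator: there is no external data.
Passing tests therefore demonstrate internal consistency of the model,
scan and inference machinery under the stated demographies — not that real
genomes behave this way.  Known simplifications: constant N with no
population-size changes; exactly two demes per pair and no gene flow
between non-sisters; uniform mutation and recombination rates along the
sequence; a single selected locus with fixed standing divergence (no
origin-time model, no multi-locus architectures); no long-range linkage
disequilibrium analysis.  The independent-pairs design reproduces each
pair's marginal statistics exactly but not cross-pair correlations a joint
phylogeny would induce.

## Numerical conventions

Windows and intervals are 0-based half-open; times are generations before
present internally, with the analysis axis in units of N.  Every stage of
every (scenario, replicate, pair) derives its seed by SHA-256 hashing of
the master seed and the stage's identifiers, so subsets rerun identically
and adding scenarios or pairs never perturbs existing results.  A failed
replicate is recorded and skipped, never imputed.
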
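# Methods

`vipadapt` quantifies how much protein adaptation is attributable to a focal
gene set — virus-interacting proteins (VIPs) — relative to the rest of a
proteome, at two time scales: the recent focal lineage (polymorphism versus
fixed differences, the McDonald–Kreitman framework) and a whole phylogeny
(aggregation of branch-site positive-selection output). Because the real
inputs (population variant panels, multi-species codon alignments, branch-site
likelihood runs) are large external resources, the package ships generators
that emulate their statistical structure with known ground truth; every
estimator is validated against those generators.

## The estimand

α is the proportion of non-synonymous (amino-acid changing) fixed differences
driven by positive selection. The classic MK estimator contrasts divergence
and polymorphism at non-synonymous and synonymous sites:

    α̂ = 1 − (D_S · p_N) / (D_N · p_S)

Slightly deleterious non-synonymous variants segregate at low frequency
without fixing, inflating p_N and biasing α̂ downward. The asymptotic variant
computes α̂(x) within derived-allele-frequency (DAF) bins and extrapolates a
fitted curve, either y = a + b·ln(x+c) or y = a + b·exp(−x/c), to x = 1.
Deleterious variants dominate only the low-frequency bins, so the
extrapolated intercept is far less biased. This implementation additionally
restricts the fit to bins wholly below DAF 0.5: ancestral-state
misassignment mirrors low-frequency variants into the high-frequency tail of
the unfolded spectrum, and the high bins are also the noisiest (fewest
variants), so they are excluded outright rather than down-weighted.

### Numerical choices in the fit

- The curve parameter c is profiled: for fixed c the model is linear in
  (a, b) and solved by least squares; c itself is found by a bounded 1-D
  minimisation of the residual sum (c ∈ [1e−3, 5] for the logarithmic form,
  [1e−2, 10] for the exponential). This removes the convergence fragility
  of joint 3-parameter nonlinear fits, which is most acute for the
  exponential form.
- The exponential form is the default; the logarithmic form is the
  fallback on non-convergence, and if both fail the last usable bin's α is
  reported with `converged=False`. The exponential saturates as x grows,
  matching the true shape of α(x); ln(x+c) is unbounded, and when α(x) has
  already flattened below the 0.5 cut (strong weakly-deleterious load, low
  true α) the logarithmic extrapolation keeps climbing and overestimates α
  — on simulated purifying-only cohorts by ~0.15–0.3, versus ≤0.05 for the
  exponential. The logarithmic form's historical appeal was convergence
  convenience, which the profiled fit makes moot.
- Fits are unweighted by default; inverse-variance proxy weights
  (p_N·p_S/(p_N+p_S) per bin) are available.
- A bin is usable with p_S ≥ 1 and ≥ 5 variants (configurable); at least
  three usable bins below the cut are required.
- α̂ is capped at 1 (its definitional maximum).
- The DAF filter for the classic test (default 0.1–0.9) is closed on both
  ends; bin intervals are half-open [lo, hi) with the last bin closed.
- Confidence intervals come from a percentile bootstrap over genes; the
  paper-style point estimate uses pooled counts (ratio of sums).

## The forward Wright–Fisher simulator

The validation design is a 400-codon, six-exon coding locus evolving for
20,000 generations in N = 1000 diploids at mutation rate 2.5e−7 per site per
generation with 10 cM/Mb recombination — a 10× time/size rescaling of
human-like parameters. One coding site in four is synonymous and only ever
neutral; non-synonymous sites draw mutation effects from a configurable mix
of neutral, advantageous, weakly deleterious and strongly deleterious
classes. True α is bookkept directly: the count of fixed advantageous
mutations over all non-synonymous fixations.

Implementation model: every mutation is an independently segregating
biallelic locus. Per generation, a derived allele at frequency p is updated
by genic selection p′ = p(1+s)/(1+ps) and binomial resampling of 2N copies;
new mutations enter as single copies at Poisson rate 2N·μ·L per class.
Selective interference between linked mutations is therefore ignored — at
the design's 10 cM/Mb the sites are close to freely recombining, and the
package asserts estimator behaviour, not absolute linked-selection effects.
The exon/intron layout and recombination rate remain in the configuration
for design fidelity but do not enter the dynamics. The inner loop is
numba-compiled.

Demography is a piecewise-constant schedule of diploid sizes; on a size
change the standing allele counts are binomially resampled to the new 2N.
The bottleneck preset crashes the population to N/5 for 500 generations
mid-window. Fixations are only counted after an optional burn-in
(equilibration takes ~4N generations; the neutral identity "substitution
rate = mutation rate" holds only at stationarity). Polymorphism is read out
as a final-generation sample of 216 haplotypes by default (a ~108-diploid
panel scale), hypergeometric per site.

Scenario presets set scaled coefficients 2Ns = +20 (advantageous), −5
(weak deleterious), −100 (strong deleterious); the class proportions
(e.g. 2% advantageous, 35% weakly deleterious in the mixed scenario) are
package choices — the validation design names the classes but not their
weights — picked so that true α falls in the informative mid-range and the
weak-deleterious load is strong enough to exhibit the classic-MK downward
bias.

### Study sizes used by the test suite

The shipped recovery study rescales further for runtime: N = 250, 200
codons, μ = 8e−6, a 1500-generation burn-in, 4000 observed generations,
100-haplotype samples, 200 loci per cohort, 20 replicate cohorts per
scenario, α(x) binned at width 0.05. Only estimator accuracy (|mean α̂ −
mean true α| ≤ 0.1 per scenario) is asserted at this scale; absolute
divergence levels are not meaningful quantities here.

## Gene cohorts and what they do (not) emulate

`generate_gene_cohort` draws per-gene records with a gamma-distributed
latent constraint factor c shared between polymorphism and divergence:
p_S ~ Poisson(θ·L/600), p_N ~ Poisson(θ·L/600 · c · (1−r)) with r the VIP
pN/pS reduction (default 0.25, the great-ape-scale effect), and
non-synonymous divergence carrying the same constraint inflated by 1/(1−α)
(defaults α = 0.27 for VIPs, 0.09 otherwise). Two consequences follow by
construction: the expected VIP/non-VIP mean pN/pS ratio equals exactly 1−r,
and pooled classic MK recovers the configured α — the generators are the
oracles for the matching and contrast machinery. Covariates (GC, length,
recombination, expression breadth, interaction degree, immune/antiviral
flags, ten virus labels) are drawn at realistic scales with VIP/non-VIP mean
pairs taken from the real cohort's reported values. GO labels follow a
module model (162 processes in 18 modules; genes draw ~5 terms from one
module) so that GO-overlap matching is feasible, as it is in real
annotations where processes co-occur.

Not emulated: linkage between genes, shared pathway structure beyond GO
modules, correlated noise between polymorphism and divergence beyond the
shared constraint factor, and segregating-site-level detail (cohort p_N/p_S
are counts, not site lists). Passing tests therefore demonstrate that the
estimators recover effects of the stated form and size, not that real-data
confounding is fully represented.

`generate_branch_table` emulates branch-site test output: per gene a latent
mean proportion of selected codons (base 0.003, lognormal spread,
multiplied by `vip_excess` for VIPs) is spread over branches as a
zero-inflated exponential (30% of branches active), with Beta(0.5, 10)
branch p-values on active branches, Bernoulli synteny masks (4% invalid),
and gene-level overall-test p-values U^(1+50·m) that shrink with true
signal. The downstream excess statistic has expectation
(vip_excess − 1)·100%.

## Matched-control resampling

VIPs are substantially more constrained than average, and branch-site test
power rises with relaxed constraint, so unmatched contrasts confound
adaptation with purifying selection. Two samplers:

**Target-average permutation.** Control genes are drawn one at a time while
the running mean of a covariate is confined to [0.95·a·m, 1.05·a·m], where m
is the focal-set mean and a a calibration fraction; every X-th regular draw
is unconstrained, and after any excursion members are drawn that
monotonically pull the mean back. X tunes the variance of the sampled
values (frequent free draws → higher variance). Implementation decisions:
the initial five members (redrawn until inside the interval) and corrective
draws do not advance the every-X counter; sampling is without replacement
within a set and with replacement across sets; each corrective/constrained
step retries up to 10⁴ candidates before failing loudly; the final member
must land inside the interval, with a bounded extreme-member swap-repair as
a last resort. The post-condition (final mean inside the interval) is
asserted on every draw.

The matching covariate for constraint control is dN, not dN/dS and not
pN/pS directly: pN/pS is too noisy per gene, while dN/dS embeds the very
adaptation signal being tested (matching on it is over-conservative, though
a dN/dS mode exists for sensitivity analyses). `calibrate_match`
grid-searches (a, X) so that matched controls reproduce the focal set's
pooled pN/pS mean and per-gene variance; the discrepancy is the sum of
squared z-scores of the mean and variance differences, and among candidates
whose control pN/pS is at least the focal value (controls no more
constrained — the conservative direction) the minimiser wins.

**GO matching.** Each focal gene is paired with a random unused candidate
sharing ≥ 60% of its GO processes (denominator: the focal gene's term
count, matching the asymmetric ≤ 140% size cap) with at most 1.4× as many
terms. The term universe can be restricted to processes with a minimum
focal-gene count (50 in the original design). Per-gene failures are
reported; the run fails only above a configurable unmatched fraction.

Permutation p-values are reported raw (k/n, so "P=0" is possible) alongside
the conservative (k+1)/(n+1), with an explicit "< 1/n" bound at zero
exceedances.

## Phylogeny-wide excess of adaptation

Per gene, the proportion of positively selected codons is averaged over
synteny-valid branches only (equal branch weights); genes with fewer than
39 of 44 valid branches are excluded, mirroring the orthology-quality rule.
Excess of adaptation is (mean_VIP/mean_control − 1)·100, computed per
overall-test p-value threshold from lenient (0.9) to strict (1e−5), with
control 95% intervals over matched sets; the decomposition splits it into
more genes with signal, more significant branches per gene, and a larger
per-branch proportion. Branch and gene p-values are consumed as given — no
re-computation, no multiple-testing correction (thresholds are on raw
p-values by design).

The interface case study relocates the set of significant codons (site
p ≤ threshold) uniformly over the coding sequence (without replacement,
preserving the count — equivalently a hypergeometric draw of in-window
hits) 5000 times by default; excess = observed/expected in-window counts,
p = fraction of randomisations ≥ observed. Neighborhoods are linear
sequence distance in codons; 3-D structural neighborhoods are out of scope.
Sequons are N-X-[S/T] with X ≠ P; gains and losses on a tree are counted
after Fitch parsimony on the rooted topology, ties broken toward the parent
state (root ties toward the majority tip state).

## Reproducibility

Every randomised routine takes a seed or Generator. The pipeline derives
per-stage seeds from a single global seed via sha256(seed:stage), records
them in the report's provenance block together with a configuration hash
(output directory excluded), and writes JSON with sorted keys so identical
configurations yield byte-identical reports. Tables are tab-separated with
round-trip float formatting.

## Known limitations

- The simulator's free-recombination approximation understates interference
  (background selection, hitchhiking); α recovery under strong linkage is
  untested.
- Site classes are assigned at the site level (one in four coding sites
  synonymous), not via a codon table; codon-aware mutation is a non-goal.
- The target-average sampler can fail on adversarial pools (e.g. target
  interval near the pool extreme); it fails explicitly rather than degrade.
- Per-gene asymptotic fits are unsupported by design — the method needs
  pooled counts from large gene sets (>~10³ genes at real-data densities).
- The calibration criterion (z-score discrepancy) is an explicit stand-in
  for what is in practice a judgement call; its grid and sample count are
  configurable.
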
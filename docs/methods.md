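# Methods

This note records the models behind `dompop`, the assumptions they
make, the defaults and why, and the numerical choices that are not
visible from the API.

## Character compatibility analysis

### Definitions

For two loci scored 0/1 across the genotypes of one population, the
pair is *incompatible* when all four ordered state pairs 0/0, 1/0, 0/1
and 1/1 occur. Under infinite-sites mutation on a genealogy a derived
state arises once, so at most three of the four combinations can exist;
observing all four requires either recombination between the loci or
recurrent/parallel mutation. The matrix incompatibility count (MIC)
is the number of incompatible unordered locus pairs.

For complete binary matrices `MIC = 0` is equivalent to the existence
of an unrooted perfect phylogeny (pairwise compatibility of binary
characters implies joint compatibility). The package exploits this for
validation: `perfect_phylogeny_check` decides tree-likeness by a
genuinely different algorithm — complement every column in which the
first genotype carries a 1 (making that genotype an all-zero root),
sort columns by descending 1-count, and verify Gusfield's
laminar-containment condition (all 1-rows of a column must point back
to the same preceding column). The equivalence `MIC = 0 ⇔ perfect
phylogeny` is asserted exhaustively over all 4×3 binary matrices and on
random matrices in the test suite.

### Analysis unit and algorithm

The unit is the **distinct multilocus genotype**, not the individual:
duplicate band vectors are presumed clones (or identical-by-descent
selfing products) and collapsed before any compatibility computation,
so deletion trajectories count genotypes. Jackknife contribution of
genotype *g* is `MIC(all) − MIC(all − g)`, which is never negative
(removing a row can only remove state combinations). The deletion loop
recomputes all contributions on the surviving matrix at every step —
"successively deleted" is read as iterative re-ranking, since a
genotype's contribution changes once another recombinant is gone — and
removes the genotype with the maximal contribution. Ties are broken
toward the genotype first encountered (smallest genotype ID); tie
steps are reported, because a different tie rule can change the
trajectory's tail even though the terminal MIC of zero is always
reached. Contributions are evaluated incrementally (subtracting one
row's outer products from the four pairwise count matrices), so one
deletion step costs O(G·L²) rather than O(G²·L²).

### Missing data

Pairwise-complete deletion: a genotype missing either locus of a pair
contributes nothing to that pair's combination set, and a pair with no
jointly scored genotype counts as compatible. This is the weakest
defensible assumption; band matrices in practice are near-complete.
Genotype collapsing treats a missing call as a state of its own — two
individuals are the same genotype only if their vectors match exactly,
missing pattern included — which can only oversplit, never chain
distinct clones together. The perfect-phylogeny oracle requires
complete data and refuses anything else, since it exists only to test
the core on simulated (complete) matrices.

### Classification

`classify_reproduction` labels a trajectory recombination-dominated
when the deleted fraction reaches the threshold (default 0.5, the ≥
rule). The threshold is a reporting heuristic extracted from the
field contrast between gradual (half or more of genotypes deleted) and
sharp (about a third) declines; it is configurable and always echoed
in the output.

## Dominant-marker diversity

Assumptions: Hardy–Weinberg proportions within populations (the same
assumption made by the f-free differentiation model below), two alleles
per locus, independence across loci for the bootstrap.

Per locus with `n` scored individuals and `m` band-absent:
`q = √(m/n)` (no small-sample correction — matching the classic
POPGEN-style default), `p = 1 − q`, `na` = number of phenotypes
observed (1 or 2), `ne = 1/(p² + q²)`, `h = 1 − p² − q²`, and the
Shannon information term `S = −(p ln p + q ln q)` in natural log.
A locus is polymorphic when both phenotypes are observed (no 95%
criterion). Population values are unweighted per-locus averages over
the loci retained for that population; only loci with zero scorable
entries are dropped.

The 95% interval for mean S is a percentile bootstrap over individuals
(default 1000 resamples, seeded). Two caveats are worth stating
plainly. First, `q̂` is biased upward at small n (E√X ≤ √EX), and the
per-locus average reduces variance like 1/√(nL) while the bias stays
O(1/n); with many loci and few individuals the interval is therefore
bias-dominated and its coverage of the generating value falls well
below nominal. The coverage experiment in the test suite accordingly
uses many individuals relative to loci (n = 400, L = 20), where the
percentile interval attains its nominal level. Second, at survey-sized
designs (20 individuals, ~100 loci) the bootstrap distribution of mean
S is visibly shifted relative to the point estimate, so the printed
interval can exclude its own point estimate — the same anomaly
reported in published dominant-marker tables; it is a property of the
estimator at that design, not a bug in the resampling.

Shannon's index is computed on the *estimated allele frequencies*
(p, q), not on the band phenotype frequencies: this is what the
POPGEN-family tools report for dominant data and what makes a locus
with q = 1/2 contribute exactly ln 2. Mann–Whitney comparisons use the
exact null distribution for tie-free samples up to n = 20 per group
and the tie-corrected normal approximation otherwise.

## Bayesian differentiation (θ^B)

### Model

Sufficient statistics are per population × locus: `n_kl` scored
individuals and `x_kl` band-absent. The f-free hierarchical
beta-binomial is

    x_kl ~ Binomial(n_kl, q_kl²)                     (HWE dominance)
    q_kl ~ Beta(π_l (1−θ)/θ, (1−π_l)(1−θ)/θ)
    π_l  ~ Uniform(0, 1),   θ ~ Uniform(0, 1)

so `E[q_kl|π_l] = π_l` and `Var(q_kl|π_l) = π_l(1−π_l)θ` — θ is F_ST in
Wright's variance-partition sense. "f-free" fixes the within-population
inbreeding coefficient at zero: band counts from the populations alone
carry essentially no information about f, and estimating it from
dominant data is not attempted (out of scope by design). The hierarchy
moment identity is verified by simulation in the tests.

### Sampler

Metropolis-within-Gibbs in the **non-centred parameterisation**
(θ, π_l, u_kl), where `u_kl = F(q_kl; a_l, b_l)` is the Beta-CDF rank
of q: Gaussian random walks on logit θ and logit u, reflected random
walk on each π_l, all step sizes tuned every 100 burn-in sweeps toward
20–40% acceptance and frozen for the sampling run (tuning during
sampling would break detailed balance). Because the ranks are iid
uniform under the prior for *any* (θ, π), holding u fixed while moving
θ or π cancels every prior term: the acceptance ratio is the binomial
likelihood ratio at the materialised `q = F⁻¹(u; a, b)` plus the logit
Jacobian.

The non-centred state is not a stylistic choice. As θ → 1 the Beta
shapes a, b → 0 and the hierarchy pushes q within ~exp(-1/a) of the
boundaries — far beyond floating-point resolution — so a random walk on
(logit) q cannot follow and, if clipped, silently truncates the target
and biases θ downward. In rank coordinates that funnel disappears; in
particular, with no observations the θ update reduces to a free
logit-scale walk whose marginal is exactly the Uniform(0, 1) prior, a
property the test suite checks with a Kolmogorov–Smirnov test on 5000
retained draws.

Defaults follow the conventional schedule for this model family:
burn-in 50 000, sampling run 250 000, every 50th draw retained
(5000 draws per chain), three replicate chains from independent
streams pooled for the posterior summaries. Reduced schedules
(2k/10k/10, one chain) are used throughout the tests and flagged in
the stored schedule field. Point estimate: posterior mean; interval:
equal-tailed 2.5/97.5 percentiles. Convergence is monitored with
split-chain R̂ on the θ draws (warning above 1.1, never an error).
Deviance summaries use the full binomial log-pmf: `Dbar` averages
−2·log-likelihood over retained draws, `pD = Dbar − D(q̄)` with q̄ the
posterior mean of the materialised q, and `DIC = Dbar + pD` (an
identity by construction, asserted in tests together with pD ≥ 0).

Pairwise estimation derives each pair's RNG stream from the run seed
and the pair's position in the sorted pair list, making
θ(A,B) ≡ θ(B,A) and every rerun bit-identical.

## The simulator

The generator produces band matrices with attached truth (diploid
genotypes for sexual modes, genealogy and sexual/clonal labels, the
generating θ for hierarchy draws). Defaults mirror a typical
dominant-marker survey: 20 individuals per population, 102 loci,
founder presence-allele frequencies drawn from Beta(1, 1); populations
are independent demes without migration.

- **Sexual modes.** Founders are drawn at Hardy–Weinberg proportions
  from per-locus allele frequencies; each of `n_generations` (default
  10) replaces the population with offspring produced by the chosen
  mode: intergametophytic crossing (two distinct parents, one gamete
  each), intergametophytic selfing (two independent gametes of one
  parent), or intragametophytic selfing (a single gamete duplicated,
  hence instant whole-genome homozygosity). Loci are unlinked —
  gametes segregate independently per locus — since ISSR bands have no
  genomic coordinates. `n_generations = 0` yields a plain HWE sample,
  the appropriate emulation of sampling few sporophytes from a large
  outcrossing stand; with the census equal to the sample size (20),
  every extra generation adds drift of order 1/(2N) per generation and
  fixes a noticeable fraction of loci, which is why high-polymorphism
  scenarios in the tests use 0 generations.
- **Clonal mode.** One (or a few) founder genets; the lineage grows by
  a sequential birth process (each new ramet copies a uniformly chosen
  existing ramet), giving a random genealogy rather than a fixed
  generation count. Somatic mutation acts directly on the band
  phenotype — ISSR band gain/loss through primer-site change — at rate
  `somatic_mu` per locus per birth (default 0.01, i.e. ~1 flip per
  birth at 102 loci, enough to give most ramets distinct genotypes as
  observed in clonally expanding stands). Under `infinite_sites` each
  flip consumes a locus never mutated before anywhere in the lineage,
  guaranteeing a perfect phylogeny (MIC = 0) by construction; with
  finite sites recurrent flips can create homoplasy.
- **Mixed mode.** A fraction `sexual_fraction` of individuals are
  recombinants formed by per-locus reshuffling of two distinct lineage
  members' band vectors (free recombination at the phenotype level).
  Deleting at most those recombinants always restores tree-likeness,
  which is the sharp-decline scenario the deletion loop must detect.
- **Hierarchy draws.** `simulate_from_hierarchy` samples (π, q, x)
  exactly from the θ^B model for parameter-recovery experiments.

What the simulator does *not* emulate: scoring error and band
homoplasy (co-migrating non-homologous fragments), linkage, migration
between demes, overlapping generations, and selection. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated models, not robustness of ISSR band calling in the field.

## Numerical and engineering choices

- Band matrices are int8 with −1 as the missing sentinel; text I/O uses
  a configurable missing code (default `?`, `NA` always accepted).
- The four pairwise combination-count matrices are computed as integer
  matrix products (presence and absence indicators), so MIC on a
  survey-sized population costs milliseconds and the jackknife reuses
  the full-matrix counts.
- All randomness flows through `numpy.random.SeedSequence` spawning:
  the pipeline derives independent streams for simulation, bootstrap
  and MCMC from one seed, so every output (including the manifest) is
  byte-identical across reruns.
- Degenerate inputs are defined, not errors: single-genotype or
  single-locus matrices have MIC 0, a fully compatible input yields an
  empty deletion order and trajectory [0], and a one-population
  pipeline run skips the differentiation stage with a logged notice.
- The classification threshold, bootstrap width, MCMC schedule and
  chain count are ordinary function arguments everywhere, with the
  defaults above.

## Known limitations

- Jackknife ranking is greedy; it makes no claim of finding the
  *minimum* set of genotypes whose removal yields compatibility (that
  problem is NP-hard in general), only a reproducible trajectory.
- MIC cannot distinguish recombination from recurrent mutation or
  scoring homoplasy; interpretation leans on the infinite-sites
  approximation being reasonable for band data.
- The diversity estimators inherit the dominance assumptions (HWE
  within populations, two alleles); with inbreeding, q̂ and everything
  downstream are biased.
- θ^B numerical agreement with any particular historical implementation
  of the same model is not claimed; correctness is established by
  prior-predictive exactness, moment checks, and parameter recovery on
  data simulated from the model.
- The bootstrap interval for mean S should not be trusted at
  few-individuals × many-loci designs (see above).
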
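# Methods

## Models and conventions

Everything is parameterized in expected mutations per site: θ = 4Nμ for
population sizes, τ for divergence times. Backwards in time, a pair of
lineages co-resident in a population of size θ coalesces at rate c = 2/θ.
The scaled migration rate M_ij = N_j·m_ij counts expected immigrants per
generation into population j from i; tracing ancestry backwards, a lineage
currently in j jumps into i at the mutation-scaled rate w_ij = 4·M_ij/θ_j
= m_ij/μ. Tips are at age 0 and time increases into the past. Conversions
to coalescent units (2τ/θ) happen only at API boundaries.

## The 21-state coalescent-with-migration chain (`gdikit.ctmc`)

For two populations and three sampled sequences (a₁, a₂ from A; b from B)
the genealogical process is a CTMC whose state records which lineages
survive and where they reside: 8 three-lineage states (`AAA`…`BBB`, demes
of a₁, a₂, b in that order), 12 two-lineage states (a coalesced pair plus a
free lineage in one of four location patterns, e.g. `AB_b` = pair in A,
b in B), and one absorbing state `A|B` after the second coalescence.

The generator is *constructed from the movement/coalescence rules*, not
transcribed from a table: each lineage in A jumps to B at w_BA (B to A at
w_AB); each co-resident pair coalesces at that deme's rate; diagonals make
rows sum to zero. Unit tests pin individual entries and the row-sum/
positivity properties, which protects against the transcription errors a
hard-coded matrix invites.

Transition probabilities use the spectral form
p_ij(t) = Σ_k u_ik v_kj e^{λ_k t} with V = U⁻¹, and the time-integrals
needed for gene-tree probabilities use
∫₀^τ p_ij(t) dt = Σ_k u_ik v_kj (e^{λ_k τ} − 1)/λ_k, with the factor
replaced by its limit τ when |λ_k| < 1e−10.

**Reliability of the eigen route.** The chain is invariant under exchanging
a₁ and a₂, so Q has *genuinely repeated* eigenvalues at every parameter
value; an eigenvalue-gap test would therefore disable the spectral path
everywhere. Repeated eigenvalues are harmless as long as the eigenvector
basis is complete, so the implemented criterion is cond(U) < 1e8 together
with ‖U·U⁻¹ − I‖_max < 1e−8; in practice cond(U) ≈ 10 across the parameter
space, including M = 0 (the reducible generator is still diagonalizable).
If the criterion ever fails, `transition_matrix` falls back to
scaling-and-squaring `expm` and the integral to adaptive quadrature of
`expm` (scipy `quad_vec`, epsabs 1e−12). Complex arithmetic is allowed
internally; outputs are asserted real within 1e−10 and truncated.

A reduced 5-state chain (one sequence per population: four location
configurations plus absorption) is built from the same rules as an
independent instantiation; it drives the pair-coalescence probability and
the coalescence-time law.

## P₁ and the gdi (`gdikit.gdi`)

Starting from `AAB`, gene tree G₁ = ((a₁,a₂),b) arises either by a₁,a₂
coalescing before τ — density
f(t) = [p_{AAB,AAA}+p_{AAB,AAB}]·2/θ_A + [p_{AAB,BBA}+p_{AAB,BBB}]·2/θ_B,
integrated via the spectral time-integral — or by all three lineages
surviving to the ancestral population, where exchangeability makes each
topology equally likely: P₁ = ∫₀^τ f + P_{AAB,S₃}(τ)/3. Then
gdi = (3·P₁ − 1)/2. Without migration, P₁ = 1 − ⅔e^{−2τ/θ_A} and
gdi = 1 − e^{−2τ/θ_A}; these closed forms double as oracles for the chain
computation (agreement within 1e−10 in tests).

The gdi is anchored on the focal population's θ; the two directions of a
pair can disagree (small-θ founder populations reach high gdi quickly), so
the API always makes the anchor explicit and the pipeline reports both
directions. Threshold mapping: gdi bounds (0.2, 0.7) ↔ P₁ (0.4667, 0.80)
↔ no-migration divergences −ln(1−gdi) = (0.2231, 1.204) coalescent units.
Note the printed 2-d.p. values 0.22/1.20 are rounded images of the exact
thresholds; evaluating P₁ at divergence exactly 0.22 gives 0.465, which is
why tests map through the exact −ln(0.8).

The default surface grid (2τ/θ ∈ [0,5] × M ∈ [0,10], 51 × 41) spans the
region where the index transitions between its limits.

## Structured-coalescent simulator (`gdikit.simulate`)

Gene trees are simulated epoch-wise on a dated species tree: within an
epoch, competing exponentials for per-pair coalescence (rate 2/θ_deme) and
per-lineage backward migration (rate 4M/θ_destination for each band whose
two branches coexist); at a species-tree node the daughter demes merge.
Migration bands are given explicitly, including bands involving ancestral
branches — band sets are user-specified, never inferred, because the set of
active bands after each merge is a modelling decision (e.g. stepping-stone
designs re-attach bands to ancestors).

The backward convention is pinned by a dedicated test: with a single
forward band A→B, only the B-resident lineage moves (into A) at rate
4M/θ_B, and the simulated first-jump times match the truncated exponential.
The (1,1)-sample coalescence-before-τ frequency and the (2,1)-sample
topology frequency are cross-checked against the analytic values within 3
Monte-Carlo SE.

Alignments evolve i.i.d. sites down the genealogy from stationary root
frequencies, using per-branch transition probabilities from the symmetrized
eigendecomposition of the JC/HKY generator (normalized to one expected
substitution per unit time); this is exact and much faster than per-site
event simulation at 500-site scales. HKY uses T,C,A,G frequency order and
κ as the transition/transversion rate ratio.

For large topology-frequency experiments a vectorized simulator of the
*embedded jump chain* of the 21-state process runs ~10⁶ loci in seconds:
exponential holding times and categorical jumps applied to whole arrays of
loci until the first coalescence or τ, surviving loci resolved as G₁ with
probability ⅓. This is the Monte-Carlo counterpart used to validate the
spectral P₁ at scale; the event-driven per-locus simulator is validated at
2×10⁴ replicates (its pure-Python cost makes 10⁶-locus runs pointless when
the jump chain is available).

## Protracted speciation (`gdikit.psm`)

The simplified model has identical initiation (λ) and extinction (μ) rates
for incipient and true species plus a conversion rate β, so a population
tree is simulated first (forward Gillespie, conditioned on survival by
rejection, capped at 1e5 attempts) and conversions are superimposed as a
Poisson process of rate β on the branches of the *reconstructed* (pruned)
tree — events on extinct lineages cannot affect tip labels, so placing
them would change nothing observable (and the event-count statistics are
reported for the reconstructed tree only). When stopping at n tips, the
final epoch is extended by the waiting time to the next (discarded) event;
otherwise the newest sister tips would sit on zero-length pendant branches
that can never carry conversions.

A conversion event makes the subtree below it a new true species until
overridden by a more recent event on the path; tips with no event on their
root-to-tip path share the ancestral status. With total branch length T, a
k-event configuration has density β^k·e^{−βT} (event-count marginal
Poisson(βT), verified by chi-square), and the joint prior factorizes into
the birth–death tree density times this conversion term. The tip species
labels are a deterministic function of the event set — sequence simulation
never reads them, which is the non-identifiability the factorization
makes explicit.

## Pairwise likelihoods and the KL best fit (`gdikit.pairwise`)

Each locus contributes two sequences (one per population) reduced to the
sufficient statistic (x mismatches, n sites); the likelihood depends only
on the histogram of x, making its cost independent of the number of loci.
Under the two-species isolation model H2 (parameters τ, θ_AB) the
coalescence time is τ + v with v ~ Exp(2/θ_AB), and per-site mismatch
probability follows the JC curve p(t) = ¾(1 − e^{−8t/3}) at one-lineage
depth t. The ancestral integral uses 64-node Gauss–Legendre after the
substitution v = θ_AB·u/(2(1−u)), which maps the exponential weight to a
smooth bounded integrand (verified against scipy adaptive quadrature to
1e−8 relative and against the n = 1 closed form to 1e−10). H1 is the τ = 0
special case.

`fit_H2` maximizes over log-transformed (τ, θ_AB) with a deterministic
multistart (τ ∈ {1e−5, 1e−4, 1e−3, 5e−3} × moment-based θ × {0.5, 2},
Nelder–Mead, fatol 1e−10) and profiles the τ = 0 boundary explicitly,
reporting it as a flag rather than a tiny positive number (H1 ⊂ H2
semantics).

The coalescence-time law under IM comes from the 5-state chain: density
p_{AB,AA}(t)·c_A + p_{AB,BB}(t)·c_B before τ, an Exp(2/θ_AB) tail after.
Its sampler inverts the CDF on a 4096-point grid (KS-tested against the
CDF at 10⁵ draws); simulated mismatch data are then Binomial(n, p(t)) —
exactly the law of JC pairwise data, without simulating alignments.

`best_fit_expected` computes the analytic mismatch distribution q(x)
under IM (128-node Gauss–Legendre against the exact chain density before
τ plus the ancestral tail) and maximizes E_q[log p(x|τ, θ_AB)] — the
infinite-data limit of the MLE, free of Monte-Carlo noise. When the
generating model is H2 itself it recovers the truth to optimizer precision
(KL = 0), and at the high-gene-flow operating point it shows τ* > 0 with
D(H1) > D(H2) > 0: the two-species model is strictly less wrong, which is
the mechanism behind asymptotic over-splitting.

## Delimitation pipeline (`gdikit.delimit`)

Posterior tables are whitespace-delimited with a header (bpp style;
arbitrary layouts via a column map). `gdi_posterior` applies
gdi = 1 − e^{−2τ/θ} draw by draw (focal θ or the mean of a θ pair);
`point_gdi` evaluates at posterior means — the two differ by a Jensen gap
and are deliberately distinct functions. Decisions use the posterior mean
by default (quantiles available): single below 0.2, distinct above 0.7.

`hierarchical_collapse` walks a guide tree: the gdi is computed for both
members of every cherry, each anchored on its own θ; a cherry collapses
only when *both* directions say single (the conservative rule — one-single
one-ambiguous does not collapse); the provider is re-invoked on the
collapsed tree until nothing collapses or the root is reached (at most
(#internal nodes) iterations). The provider abstraction decouples the
pipeline from any MCMC engine: providers may read sample files or call the
synthetic generator — running an external Bayesian program is out of
scope, so pipeline tests use synthetic posteriors whose (τ, θ) encode the
scenario under study.

`synthetic_posterior` draws seeded columns from named distributions with
ancestor ≥ descendant ordering enforced by rejection.

## What the synthetic data do and do not show

The generators reproduce the *model's own* assumptions: neutral loci,
free recombination between and none within loci, constant θ per branch,
time-constant migration, JC/HKY sites, and (for pairwise fitting) the
exact JC binomial law. Passing tests therefore demonstrate internal
consistency and correct mathematics, not robustness to rate variation,
selection, linkage, or model misspecification beyond the IM-vs-isolation
case that is the point of the asymptotics experiment. Posterior samples
consumed by the pipeline are synthetic or external: the package does not
run MCMC, so full-posterior delimitation results depend on whatever
engine produced the samples.

## Problem sizes and numerical choices

- Asymptotics experiment: 10⁵ loci × 500 sites (the histogram reduction
  makes the fit cost independent of L); the infinite-data τ* uses exact
  quadrature instead of the 2×10⁵-locus route, the package's preferred
  noise-free formulation.
- Analytic-vs-simulation validation: 2×10⁵ jump-chain genealogies per grid
  cell, 3 Monte-Carlo-SE tolerance.
- Quadratures: 64 nodes (ancestral integral; doubling changes log-likelihood
  < 1e−6 at the tested operating points), 128 nodes (pre-τ density);
  spectral integrals exact up to eigensystem conditioning.
- Degenerate inputs: τ = 0 returns P₁ = ⅓ exactly; M = 0 pair-coalescence
  probability is 0 by construction; gdi = 1 maps to an infinite
  coalescent-unit bound, reported as `inf`.
- Seeds: every stochastic routine takes a `numpy.random.Generator`;
  file-writing runs record their seed in a manifest.

## Known limitations

- Chains cover ≤ 3 sequences and 2 demes; larger samples per species are
  simulated but have no analytic P₁.
- gdi is defined for the (2,1) sample configuration; multi-population
  indices are out of scope.
- Pairwise likelihoods are JC-only (HKY data can be simulated but the
  pairwise fit ignores the distinction, as in the experiment it supports).
- The PSM is the simplified equal-rates variant; β is never inferred.
- No MCMC: the delimitation pipeline consumes posterior samples produced
  elsewhere.
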
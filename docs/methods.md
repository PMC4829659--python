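# Methods

## The model

`trophodiv` analyses trait-dependent diversification for a discrete
character with k states (here: dietary guilds).  Each state i has its own
speciation rate λ_i and extinction rate μ_i (per lineage per unit time), and
lineages switch states along branches with Markov transition rates q_ij.
The model's likelihood on a rooted binary ultrametric tree with observed tip
states is computed by the pruning algorithm: along every branch the coupled
system

    dE_i/dt = μ_i − (λ_i + μ_i + Σ_j q_ij) E_i + λ_i E_i² + Σ_{j≠i} q_ij E_j
    dD_i/dt = −(λ_i + μ_i + Σ_j q_ij) D_i + 2 λ_i E_i D_i + Σ_{j≠i} q_ij D_j

is integrated tipward → rootward (E_i: probability a lineage in state i
leaves no sampled descendants; D_i: likelihood density of the subtended
data), daughter solutions are joined at each node with the factor λ_i, and
the root D vector is aggregated.  Tips initialize D_i = f_i at the observed
state (f_i: per-state sampling fraction, default 1) and E_i = 1 − f_i;
unknown tip states set D_i = f_i for every i.

Numerics: an adaptive embedded Cash–Karp Runge–Kutta 4(5) pair (defaults
rtol 1e-8, atol 1e-10), compiled with numba.  D is rescaled to max 1 at
every node (and mid-branch if it falls below 1e-150), with the log factor
accumulated, so likelihoods of large trees never underflow.  E is checked —
not clamped — to stay in [0, 1] up to the solver's own error scale; a
violation or a step-size underflow raises an error.  Integration tolerances
are options; the MCMC-heavy validation runs use rtol 1e-6 / atol 1e-8,
whose likelihood error (~1e-5 log units) is far below Monte-Carlo noise.

Root treatment defaults to data-weighted averaging (weights ∝ the root D
vector) with conditioning on survival (division by λ_i (1−E_i)² before
weighting); both are switchable (`LikelihoodOptions`).  Zero-length branches
integrate trivially; polytomies are rejected rather than silently resolved,
because resolution changes the likelihood.

The implementation is validated against three independent oracles kept in
`trophodiv.reference`: a fixed-step RK4 brute-force integrator, the
closed-form constant-rate birth–death likelihood (k = 1), and an
expm-pruning likelihood for a neutral character; with state-independent λ
and μ the k-state log-likelihood must equal birth–death + neutral-character
log-likelihoods, which it does to < 1e-6.

## Bayesian inference

Rates get half-Cauchy priors with location 0 and a family-specific scale
(one scale each for the λ, μ and q families) that is itself estimated — a
hierarchical prior that keeps rates small-but-positive and shrinks
weakly-informed states toward their family's typical magnitude.  The scale
parameters live on configurable bounds [1e-4, 1e2] with a **uniform**
hyperprior by default.  A log-uniform scale prior is also available, but it
is not the default because its marginal over each rate behaves like 1/rate
inside the band: in recovery experiments it pulled weakly-identified
extinction rates so strongly toward zero that 95% credible intervals
excluded the simulating values (μ-class coverage 6/8 versus 8/8 with the
uniform prior on identical trees, with maximum-likelihood estimates on the
same trees unbiased).

Sampling is univariate slice sampling (stepping out + shrinkage) on the
natural scale, cycling over all rates and the three hyper-scales; widths are
auto-tuned during burn-in and then frozen.  One *step* is a full update
cycle; every `thin`-th cycle is retained, so a chain of S steps keeps
⌊S/thin⌋ samples (the headline configuration, 1,500,000 steps thinned every
1,000th, keeps 1,500).  Default burn-in removes the first 10% of retained
samples per chain.  Chains are exactly reproducible under a seed and report
effective sample sizes (via arviz).

Phylogenetic uncertainty is handled by fitting each tree of a tree set
independently and concatenating the burned-in traces into one posterior per
parameter (`combine_traces`; mixed-k traces are refused).  Net
diversification r_i = λ_i − μ_i is computed per retained sample.  Credible
intervals are highest-posterior-density intervals from the
shortest-sorted-window algorithm; a multimodal posterior still yields a
single interval (known limitation).  Guild comparisons take per-sample
differences (guild − focal) for λ, μ and r and flag a difference significant
at a level when 0 lies outside that HPD interval (95/90/80%).

## Simulation

Trees are simulated by a Gillespie event walk from a single stem lineage:
per-lineage rates λ_s (birth), μ_s (death), q_sj (state flip).  Stop rules:
a fixed time horizon, or a target tip count sampled at the moment the
(n+1)-th birth would occur (avoiding the bias of stopping exactly at the
n-th birth).  Extinct lineages are pruned; the returned tree is rooted at
the first bifurcation with surviving descendants on both sides (the
complete tree is available for diagnostics).  A neutral (Mk) character
simulator evolves a state along a fixed tree's branches as a continuous-time
Markov chain.

Two simulation-based checks mirror the pipeline's auxiliary analyses: a
posterior-predictive *adequacy* test (simulate n trees under fitted rates,
flag whether each empirical tip-state proportion falls inside the simulated
2.5–97.5 percentile envelope) and a *neutral-character* test (simulate a
diversification-neutral character with fitted transition rates, refit the
full model, and report how often any between-state λ/μ difference is flagged
— the false-positive propensity of the machinery on rate-heterogeneous
trees).

## Transition network

The guild-level transition network has guilds as nodes and posterior median
transition rates as directed link weights.  Centrality is eigenvector
*in*-centrality — x_j ∝ Σ_i w_ij x_i, the leading eigenvector of the
transposed weight matrix — computed by power iteration (uniform start,
tolerance 1e-12, period-2 oscillations averaged, persistent non-convergence
an error) and reported normalized to max 1.  The permutation null
redistributes the multiset of off-diagonal weights over the off-diagonal
positions (topology fixed, values shuffled, sampling without replacement)
and recomputes centralities; p_j = (1 + #{null_j ≥ obs_j}) / (1 + n_perm).
The comparison uses 2-norm-normalized centralities: under max-normalization
every replica's most central node is exactly 1, so the most central observed
node could never attain p below ~1/k; the 2-norm profile preserves the
concentration signal the test is after while ordering nodes identically.
Any display cutoff (e.g. hiding links < 0.001 in a figure) affects rendering
only, never the test.

## Diet space and guild classification

A species' diet is a 9-item score vector summing to 10.  Classification:
exactly one item with score strictly > t (default t = 5) makes the species
that item's specialist; otherwise (flat diet or tie) it is an omnivore, and
a dominant "miscellaneous" score also maps to omnivore since no guild is
defined for it.  The strict inequality is what makes the 5/5-tie rule and
the >5 rule mutually consistent.  Raising t gives a more inclusive omnivory
(the sensitivity variant); the omnivore count is monotone non-decreasing
in t.

Diet similarity uses a covariance PCA of the score vectors (all nine items
share the 0–10 scale, so correlation scaling is unnecessary and would
distort the compositional structure; sign convention: each component's
largest-magnitude loading is positive).  Pairwise Euclidean distances in the
first three components are averaged within guilds (n(n−1)/2 pairs) and
between guilds (n_a·n_b pairs); standard errors are over pairs.  Item-score
histograms for a guild subset (typically omnivores) report counts of species
per score value per item.

## Phylogenetic signal (D)

For a binary trait, d_obs is the sum over internal nodes of |v(left) −
v(right)|, where tip values are the trait and internal values are recursive
child means.  D scales d_obs between two simulated references on the same
tree: random shuffles of the tip values (D = 1) and unit-rate Brownian
motion thresholded at the observed prevalence (D = 0), with the minority
state mapped to the upper tail so the statistic is exactly invariant to
swapping state labels.  p(vs random) is the add-one-corrected fraction of
shuffles with d ≤ d_obs; p(vs Brownian) the fraction of Brownian replicates
with d ≥ d_obs.  The estimator is calibrated to its own references (mean D
over replicates ≈ 1 for shuffled and ≈ 0 for Brownian-threshold traits), so
the scale is interpretable even though nodal-value conventions differ
slightly among published implementations.  A convenience wrapper encodes a
guild one-vs-rest and averages D across a tree set, reporting per-tree
significance flags and their majority.

## The synthetic-study generator

`generate_study` emulates a complete study: n_trees trees simulated
independently under known rates (independent re-simulation, rather than
perturbations of one tree, is the honest analogue of posterior tree
uncertainty for testing trace combination), tip guild labels, and a diet
table drawn so the classifier recovers every tip's guild exactly —
specialists get their focal item uniform on {6..10} with the remainder
spread over the other items (each part ≤ 4), omnivores get capped
compositions with maximum item ≤ 5.  Integer scores by default,
real-valued optional.  The ground-truth record (parameters, seeds, per-tree
state proportions, tip guilds) suffices to re-derive every expected
downstream answer.

`sink_scenario_default` is the generator's flagship regime: guilds
(insectivore, frugivore, granivore, omnivore) with λ = (0.30, 0.30, 0.30,
0.10), μ = (0.05, 0.05, 0.05, 0.20), q = 0.01 everywhere except 0.10 into
the omnivore sink — so the sink has negative net diversification (−0.10 vs
+0.25) and ten-fold elevated inflow, and is maintained by transitions rather
than by its own diversification.  Four guilds rather than a minimal three:
with three guilds the network has only six links and the sink's permutation
p-value cannot fall below ~1/15, too coarse for a test at α = 0.05; twelve
links resolve small tail probabilities.  Default sizes: 5 trees × 400 tips,
master seed 1234, root state a specialist.

## What the synthetic data do and do not show

The generator produces clean, completely sampled, correctly classified,
one-character data under exactly the fitted model.  Passing tests therefore
demonstrate correctness and calibration of the machinery — not robustness
to the features of real data it does not emulate: taxonomic insertion of
unsequenced species, backbone topology uncertainty correlated across trees,
diet misclassification, incomplete sampling, or rate heterogeneity from
unmodelled characters (the neutral-character test probes only the last).

## Desk-scale validation sizes and known limitations

The validation suite and `scripts/acceptance.py` run the full machinery at
desk scale: recovery uses 2-state trees of 300–600 tips with ~1,200-sweep
chains (posteriors verified stable against 8,000-sweep chains); the sink
check uses studies of two 300-tip trees with combined traces; the adequacy
check uses 100-tip trees against 200-tree envelopes; permutation and D
calibrations use their full replicate counts.

Two behaviors at these sizes are worth stating plainly.  First, per-state
extinction rates on moderate reconstructed trees are weakly identified: λ−μ
is well resolved, but μ itself has wide, sometimes ridge-shaped posteriors,
and states with few tips can carry inflated μ medians (high-turnover
excursions the heavy-tailed Cauchy prior barely restrains).  In the sink
regime the sink's *net diversification* rank is recovered essentially always
(16/16 in pilots), while the sink's *extinction* rank is recovered in only
roughly half of desk-scale studies — resolving per-state extinction ranks
reliably requires much larger trees and many more combined trees than a
desk-scale run affords.  Second, the adequacy self-consistency rate sits at
its nominal 95% by construction, so a check demanding ≥95% is borderline by
design.
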
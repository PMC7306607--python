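# Methods

## The model

Each of L tool-use modes is a binary trait of a lineage, acquired
irreversibly: a lineage's repertoire is a vertex of the L-dimensional
hypercube, and evolution is a monotone Markov walk from the all-zero
("toolless") state towards the all-ones state, acquiring one mode per step.
Trait loss is outside the model by construction.

Acquisition of mode *i* from state *s* carries rate

    r_i(s) = exp( θ_ii + Σ_{j ∈ s} θ_ij )

so the diagonal of the L×L parameter matrix θ holds base log-rates and the
off-diagonal θ_ij is the additive log-rate modification to mode *i* once
mode *j* has been acquired (the two-way parameterization standard for
hypercubic trait-accumulation models; a first-order, diagonal-only variant
is obtained by constraining proposals, but the two-way form is the default
because bimodal acquisition orderings — the signature of competing
pathways — require inter-trait influences). Only acquisition *orderings*
are of scientific interest here, so the continuous-time process is reduced
to its embedded jump chain: step probabilities are the rates normalized
over the absent modes, and absolute dwell times are never modelled.

## Data model and the two inheritance limits

The raw input is a taxa × modes table with entries 0 (absent), 1 (observed
in the wild), 2 (observed, human influence not excludable), plus per-taxon
annotations (aquatic / primate / bird flags and the taxonomic rank of the
observation). Binarization keeps wild observations always and
human-influence observations behind a flag (default: included; the
wild-only contrast is a standard subset analysis).

A likelihood unit is a transition observation (ancestor state, descendant
state) with ancestor ⊆ descendant. Because the data are cross-sectional,
the true inheritance pattern is unknown; the pipeline brackets it with two
limiting cases rather than estimating it:

* **inherited** — ancestral states on a supplied taxonomy are the
  elementwise AND of each node's mapped descendants. AND is the unique
  maximal reconstruction that never asserts an acquisition no descendant
  displays, and it is deterministic; no likelihood-based ancestral
  reconstruction is attempted. Observations mapped to internal nodes (the
  catalogue reports some groups at order level) constrain those nodes
  directly. Each tree edge then contributes one transition observation;
  edges with identical endpoint states are kept (they contribute
  likelihood 1) so dataset weights are stable across subsets.
* **convergent** — every taxon contributes one transition from the
  all-zero state, treating all acquisitions as independent.

Agreement between the two limits (checked on synthetic tree-structured
data, where it holds with ordering-rank correlation ≥ 0.8–0.9) means
conclusions do not hinge on the unknown inheritance pattern.

## Likelihood: importance-sampled hitting probabilities

The likelihood of a transition observation is taken proportional to the
probability that a walk from the ancestor passes through the descendant.
At L = 22 this hitting probability cannot be computed exactly (2^22
states), so it is estimated by hypercubic transition path sampling: walks
are forced to move only towards the descendant (proposals restricted to
its absent-mode set, re-normalized), and each step multiplies the walk's
importance weight by the compatible-move probability mass β. The product
of βs over a walk is an unbiased estimator of the hitting probability;
every sampled walk terminates at the target, so estimates are strictly
positive whenever rates are finite. Weights are accumulated in log space
(raw products underflow at L = 22), and a dataset's log-likelihood is the
weight-sum of per-observation log estimates.

For small state differences (≤ 14 modes by default, ≤ 16384 sublattice
states) an exact dynamic program over the sublattice between ancestor and
descendant serves as an independent oracle. Tests verify the estimator is
unbiased against it (estimates within 3 estimated standard errors on
random instances) and that its variance scales as 1/n_paths. Under the
uniform model (θ = 0) the importance weights are analytically
deterministic — the estimator is *exact* — so agreement checks there use
an absolute floor (1e-9) instead of dividing one rounding error by
another.

## Inference

Posterior sampling uses pseudo-marginal Metropolis–Hastings: a fresh
unbiased likelihood estimate is drawn for every proposal, which leaves the
exact posterior invariant at the cost of extra acceptance noise. Fixed
auxiliary seeds per θ were deliberately not used; correctness is easier to
reason about than variance, and the per-observation path count (default
200 during MCMC, 10^4 for reported likelihoods) controls the noise.

Priors are independent uniforms on [−10, 10] per θ entry — the problem dictates no
prior, so a wide flat box is the least-informative bounded choice, configurable. Proposals are a single
symmetric Gaussian perturbation of the whole matrix (default scale 0.05;
pilot-tuned per experiment to acceptance rates of roughly 0.1–0.6). No
adaptation: a fixed kernel makes every run bit-reproducible from its seed,
which the robustness machinery exploits (chain seeds are derived from a
content hash of the input matrix, so a zero-rate perturbation cell
reproduces its reference run exactly). Chains store their final state,
current likelihood estimate, and generator state, so a continued chain is
bit-identical to a single longer run. Default desk-scale lengths are
5×10^4 iterations with half discarded as burn-in and ~500 retained draws.

A validation-only exact-likelihood chain (the sublattice DP in place of
the estimator) is available for small L; the pseudo-marginal chain agrees
with it within joint Monte Carlo error on parameter means and to mean
total variation < 0.05 on ordering matrices.

## Posterior summaries

* **Ordering matrix** — entry (m, k) is the posterior probability that
  mode m is the k-th acquisition on a lineage from the empty state,
  estimated by simulating full walks under each retained θ draw (default
  20 per draw) and counting (mode, step) incidences. Every full walk
  acquires every mode exactly once, so rows and columns sum to 1 exactly,
  not just in expectation.
* **Pathway graph** — visited states and single-acquisition transitions
  with traversal frequencies; untrimmed, inflow equals outflow at every
  interior node exactly. Trimming edges below a frequency threshold
  (default 0.01 of simulated paths) exposes the high-probability branch
  structure; nodes matching observed taxa are flagged.
* **Bimodality flags** — a mode's ordering row is smoothed with a Gaussian
  kernel and local maxima above 0.25 of the row maximum are counted; two
  or more peaks flag the mode. The default bandwidth is min(1.5, L/10)
  steps: 1.5 resolves well-separated peaks at L = 22, but a fixed wide
  kernel provably merges genuine two-peak rows on small hypercubes. The
  published analyses flag bimodality visually; this score is a
  reproducible proxy, and flags at non-default settings are the user's,
  not the catalogue's.
* **Classes 1–4** — quartiles of posterior mean acquisition step (ties
  broken by input mode order; class sizes differ by at most one). The
  original early-to-late classes are qualitative; quartiles are a
  deterministic operationalization, and the full matrix is always emitted
  alongside so no information is lost to the heuristic.
* **Comparisons** — per-mode mean-step differences and total-variation
  distances between two ordering matrices, plus the Spearman correlation
  of mean-step rankings (symmetric). Two matrices whose rankings are both
  fully tied (e.g. two uniform-model runs) compare as correlation 1.

## Predictions

Both predictors pool full walks simulated under the posterior.

* **Unobserved presence** — a visited state is *compatible* with a group's
  observation if it contains every observed presence (recorded absences
  may be unobserved modes). The presence probability of an unobserved
  mode is its frequency among pooled compatible state-visits. Because
  walks are monotone, compatibility is permanent once attained and each
  state is visited at most once per walk, so the pooling reduces to a
  closed form over acquisition positions. Default pooling counts each
  compatible state-visit once; a one-vote-per-walk variant is exposed
  (`per_path=True`) since the catalogue text does not fix the weighting.
  This adopts a uniform prior over which absences are truly unobserved
  presences; expert per-cell priors can reweight the output table.
  Presence probabilities above 0.90 are highlighted by default.
* **Next acquisition** — whenever a walk occupies exactly an observed
  state, the next acquired mode is recorded; counts normalize to a
  distribution conditional on visitation, reported with the visitation
  frequency. Mode-rich states on diffuse posteriors may never be visited
  within the path budget; such rows are reported missing rather than
  imputed.

No feasibility screening is applied — a predicted mode may be
anatomically implausible for a group; that judgement is left to priors.

## Synthetic data and study conditions

The generator samples each taxon's row as a truncated prefix of a monotone
walk under a known θ (stop sizes uniform on a configurable range, default
[0, L] — the simplest exchangeable stop rule), or, in tree mode, walks
along a supplied taxonomy with each child extending its parent's path
(0–2 new acquisitions per edge by default), yielding genuinely inherited
structure. Ground truth (θ, per-taxon full acquisition orders, pathway
labels) is always returned beside the matrix so recovery scoring never
re-derives it. Perturbation operators mirror the standard observation-
noise battery: random added positives (unobserved behaviour), random
flips, and systematic undersampling of chosen modes.

The two-pathway regime splits modes into two sets with within-set
facilitation +s and cross-set suppression −s, so a walk's first step
commits it to one pathway. Two further diagonal elements are part of the
design, both scaled with s (so s = 0 is exactly the uniform model): a
within-set base-rate ramp (−r·s/5 for the r-th mode of a set) giving each
pathway a strict internal order, and a prevalence offset (−0.17·s on the
second set, ≈70/30 pathway split at s = 5). Without the ramp every mode's
marginal mean acquisition order is identical by exchangeability and
"recovering the generating order" is ill-posed; without the offset the
r-th modes of the two sets re-tie. A fully symmetric variant is available
(`within_gradient=0, imbalance=0`). Every mode remains
pathway-discriminating: early on its own pathway, late on the other,
hence bimodal.

Benchmark problem sizes (chosen once as desk-scale study conditions): the
two-pathway recovery runs L = 8, 40 taxa, strength 5, a 5×10^4-iteration
chain; the robustness grid runs L = 8 with 20 taxa — preserving the
catalogue's taxa-per-mode ratio (≈1.8) — rates {0, 0.1, 0.2}, five
replicates per cell, 10^4-iteration chains; the inheritance comparison
runs a 24-leaf random taxonomy with 2×10^4-iteration chains. A graded
first-order θ (base log-rate −0.6·i) is used where an identifiable
generating order is needed without pathway structure.

## What the synthetic fixtures do and do not show

The packaged trait matrix carries the real catalogue's 22 mode names
(affix first, matching the standard column order) over 27 coarse animal
groups with plausible wild/human-influence patterns, a matching Newick
taxonomy, and annotation flags; it is a synthetic stand-in assembled from
groups and behaviours named in the source literature, not a transcription of
any published observation table, and analyses of it demonstrate the
machinery rather than reproduce published posteriors. Likewise the
generators are mechanism-faithful, not data-faithful: they emulate
monotone accumulation, heterogeneous sampling depth, inheritance vs
convergence, competing pathways, and observation noise, but not the real
catalogue's marginal statistics, observer-effort structure, or mode
correlations. Passing tests therefore certify the estimator, the chain,
and the summaries — not any empirical claim about animal behaviour.

## Numerical choices

* Log-rate vectors are maintained incrementally during walks and
  re-centred by the running maximum over absent modes before
  exponentiation, so rate sums never overflow even at the prior bounds.
* Walk randomness is pre-drawn (one uniform per step) from the caller's
  numpy Generator and consumed in a fixed order inside compiled kernels;
  all stochastic stages take explicit seeds and no global random state is
  used anywhere.
* Categorical draws use strict-inequality cumulative comparison, so a
  zero-probability mode is never selected.
* The exact-DP oracle refuses sublattices beyond 2^14 states and
  recommends the sampler instead.
* Degenerate transition observations (ancestor = descendant) contribute
  exactly zero log-likelihood; out-of-prior proposals are rejected without
  spending a likelihood estimate.

## Known limitations

* No trait loss, no three-way or higher interactions, no time
  calibration, no model selection between parameterizations.
* The inherited limit trusts the input taxonomy topology; inconsistent
  internal-node observations (an ancestor asserting a mode its descendant
  lacks) are an error, not reconciled.
* Pseudo-marginal acceptance degrades if per-observation path counts are
  set far too low for a dataset; the acceptance rate is reported in every
  posterior's metadata and should be inspected.
* Next-acquisition predictions are undefined for states the simulation
  never visits; raising `paths_per_sample` helps only polynomially while
  state-space volume grows combinatorially.
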
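# Methods

## Model

Each candidate intron site is a binary character (0 absent, 1 present)
evolving independently down a rooted, possibly multifurcating species
tree. The root state is Bernoulli(π). The edge into node *v* carries two
parameters: a **length** ℓ ∈ [0, 10], the expected total event intensity
(gain + loss) on the edge, and a **rate ratio** r ∈ [0, 1], the gain
fraction of that intensity. A site's effective intensities on the edge
are a = γ·ℓ·r (gain) and b = ν·ℓ·(1−r) (loss), where γ and ν are
site-specific multipliers drawn from discretized Gamma distributions
with mean 1 (Yang-style equal-probability bins, bin means renormalized
to average exactly 1). The two-state chain run for unit time gives

    P(0→1) = a/(a+b) · (1 − e^−(a+b)),
    P(1→0) = b/(a+b) · (1 − e^−(a+b)),

with the identity matrix in the a+b → 0 limit. Tests verify this form
against numerical matrix exponentials, and the full pruning likelihood
against exhaustive enumeration over all node labelings.

By default only the loss rate varies across sites (`k_gain=1`,
`k_loss=4`): for intron presence/absence data, loss-rate variation is
the component of rate heterogeneity with demonstrable impact on model
fit, while gain-rate variation adds nothing detectable. The gain and
loss category axes are independent and form an equal-weight
`k_gain × k_loss` grid.

### Observability correction

A column with no presence in any extant species cannot enter a table of
intron positions. The dataset likelihood is therefore conditional on
observability: each column contributes log L(column) − log(1 − p0),
where p0 is the all-absent probability. Conversely, ancestral introns
that left no extant trace are reintroduced: in expectation as
E[M] = N·p0/(1−p0) (ML path), or by drawing M from a negative binomial
with N successes and failure probability p0 and sampling M all-absent
histories (MCMC path).

## Inference paths

**Maximum likelihood** (`intronevo.ml`). The observability-conditioned
log-likelihood is maximized by L-BFGS-B in smooth scaled-logit
coordinates (so the search never leaves the prior support and the
objective stays finite), with a deterministic heuristic start
(π=0.5, ℓ=0.5, r=0.2, shapes 1) plus seeded random restarts
(`n_starts`, default 5), keeping the best. Convergence uses scipy's
`ftol=1e-9`; duplicate columns are collapsed to unique patterns with
multiplicities, which is exact for i.i.d. columns. Ancestral
reconstruction at fixed parameters is exact: an inside–outside pass
yields per-site presence posteriors at every node and joint
parent/child distributions on every edge, mixed over rate categories by
their per-column posterior weights; expected counts add the
E[M]-weighted all-absent posterior.

**MCMC** (`intronevo.mcmc`). Metropolis–Hastings over θ with flat
priors (π, r on [0,1]; ℓ and Gamma shapes on [0,10]) and multiplicative
block proposals: one block (π | shapes | a random subset of lengths |
a random subset of ratios) is chosen uniformly, each scalar multiplied
by exp(U(−δ, δ)); the Hastings correction is the sum of log
multipliers; out-of-support proposals are auto-rejected. δ (default
0.5) adapts toward ~30% acceptance during burn-in only, preserving the
asymptotic target. At each retained step all site histories are drawn
by stochastic mapping (per-column category draw from posterior weights,
postorder conditional likelihoods, root draw, preorder child draws) and
the all-absent augmentation is sampled; per-node counts and per-edge
gain/loss tallies are recorded. Multiple chains (default 4; the
100-chain convention is configurable) are seeded deterministically from
one master seed; summaries report medians, central 95% intervals, and
Gelman–Rubin potential scale reduction per parameter. Chains start from
prior draws by default; validation experiments warm-start at the ML fit
to shorten burn-in (the stationary distribution is unchanged).

The kernel was verified exactly on a reduced target: a 3-leaf model
with two free parameters on a coarse grid gives total-variation
distance < 0.02 between visited frequencies and the grid-normalized
posterior at 1e5 steps, and prior-drawn-truth calibration on a 3-leaf
model yields nominal 95% interval coverage.

**Dollo parsimony** (`intronevo.dollo`). Presence is placed on the
minimal connected subtree spanning all unambiguous presence leaves; one
gain on the edge into its MRCA; a loss on each edge leaving the subtree
toward at least one unambiguous absence. Ambiguous leaves impose no
constraint and all-ambiguous subtrees carry no loss evidence. This
matches an exhaustive minimal-loss search (at most one origin, losses
counted toward unambiguous absences, ties broken by minimal presence)
on all small instances tested.

## Densities and reports

Counts convert to intron densities (introns per kbp of coding
sequence) by `count · ref_density / ref_count`, anchored to a reference
species present in the table; defaults are the human anchor values
(875 introns in the reference table, 6.946 introns/kbp). Branch
percentages follow the convention gain% = 100·gains/child count,
loss% = 100·losses/parent count. Display rounding is densities to one
decimal and percentages to integers; machine-readable outputs keep full
precision.

## Synthetic data

The generator draws site histories down the tree under the model and
rejects all-absent draws, so emitted tables follow the conditional law
L(pattern)/(1−p0) that the likelihood assumes (verified by chi-square
on pattern frequencies). Rejected draws are real-but-invisible sites:
their histories are tallied into the simulation truth so that
augmentation-aware estimators have an unbiased target, with the
sequential-draw semantics (rejections strictly before the Nth accepted
column) reproduced exactly. Sites are assigned round-robin to genes;
phases are i.i.d. with default mix 2:1:1 (phase 0 twice as common),
the ratio characteristic of most eukaryotic lineages.

Default generating parameters are loss-dominated — lengths U(0.1, 1.0)
and gain fractions U(0.05, 0.35) per edge, π = 0.6, loss shape 1 with 4
categories — an intron-rich ancestor bleeding introns at
lineage-specific rates, the regime reconstructed for real eukaryotic
data. Validation trees use a trifurcating root by default, mirroring
the unresolved supergroup split in the canonical phylogeny.

Model-violation scenarios: **missing orthologs** erase whole
(species, gene) blocks to `*` with a given probability (default 0.15);
**heterotachy** multiplies each edge's gain and loss intensities by
independent median-1 lognormals (σ default 0.5) and each length by a
unit-mean exponential, clipping back to the prior support with a
reported clip count. The σ and the exponential scale are this package's
choices; the granularity is per edge per replicate, the simplest
violation of rate constancy.

What the generator does **not** emulate: alignment error, non-binary
ambiguity structure (every `*` is equally uninformative), linkage
between sites of one gene (histories are independent given the gene
grouping used only for erasure), and phase-dependent rates. Passing
validation therefore demonstrates correctness of the inference under
the model's own assumptions and its robustness to the two stated
violations, not robustness to everything real data can do.

## Problem sizes and numerical choices

Desk-scale validation defaults are 8-leaf trees and 1000–2000 sites
with 20–50 replicates; chain lengths in the validation experiments are
reduced (10⁴-scale steps, single warm-started chains) relative to the
100 × 50,000-sample convention of a full analysis. Likelihoods are
computed with per-node rescaling (exact log bookkeeping), so ~100-leaf
trees pose no underflow risk; a numba-compiled pruning kernel and
unique-pattern compression keep a likelihood evaluation at ~0.5 ms on
desk-scale problems. Degenerate inputs are defined everywhere: zero
edge intensity gives the identity transition matrix; p0 = 1 raises an
error (the model admits no observable data); zero-likelihood columns
raise rather than return −inf silently.

## Known limitations

- With few leaves (≤ ~10) and flat [0,10] priors over dozens of edge
  parameters, the joint posterior carries substantial prior volume:
  its root-count marginal can sit noticeably above the maximum-
  likelihood value even when chains from independent starting points
  agree (posterior mean log-likelihood ≈ max − d/2, the Gaussian
  signature). Credible intervals are honestly Bayesian — calibrated
  over prior-drawn truths — but their frequentist coverage at one fixed
  generating truth can fall below nominal at desk scale. At the scale
  the model is meant for (many dozens of taxa), data dominate and the
  ML and Bayesian answers coincide closely.
- Stochastic mapping stores conditional likelihoods for all nodes ×
  categories × sites; at the full empirical scale (~200 nodes × 8
  categories × ~8000 sites) this is a few GB and would want chunking,
  which is not implemented.
- Dollo parsimony is included as the comparison baseline only; no
  weighted-parsimony variants.
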
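# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `fluxrevert`, in the order the pipeline runs.

## Model conditioning

A genome-scale model is assumed to carry metabolite formulas, GPR rules and
subsystem labels.  Exchange reactions are identified structurally as
boundary drains (exactly one participating metabolite).  Every exchange of a
metabolite with at least one carbon atom is treated as a carbon source and
its uptake capped at 10 mmol·gDW⁻¹·h⁻¹; CO₂ and bicarbonate are exempt,
matched both by id pattern and by formula, since fixing them is not a
realistic carbon supply for a heterotrophic cell.  Metabolites without a
parseable formula are treated as non-carbon with a warning rather than an
error, because genome-scale reconstructions routinely contain a few
unannotated species.  Only the uptake direction is touched; secretion
bounds are left at the reconstruction's values.

Flux consistency is the workhorse predicate: a reaction is *blocked* when it
cannot reach |v| ≥ 10⁻⁶ in any feasible steady state (both directions are
probed for reversible reactions).  The consistent subnetwork is computed by
per-reaction flux-variability analysis iterated to a fixed point; removal of
a blocked reaction never changes the feasible set of the remainder, so the
loop converges after one or two passes.  The 10⁻⁶ activity threshold is the
single global tolerance: it also decides functionality ("can this sink carry
flux?"), the perturbation noise floor, and the growth-ratio equality test.

## Expression preprocessing

The pipeline order is fixed and idempotent from the merge step onward:
drop all-missing rows → 50%-replicate filter → per-stage imputation →
replicate mean → log₁₀ → intersection with model genes.  Imputation follows
a two-branch rule: a stage observed in ≥50% of its replicates has its gaps
filled with the stage mean; a stage below that bar is replaced wholesale by
the global minimum of the filtered matrix.  Whether an observed singleton in
a failing stage should survive is genuinely ambiguous; we replace it (the
stage evidently failed quality control) but expose
`impute(..., replace_whole_stage=False)` for the other reading.

Differential expression uses Welch's unequal-variance t-test with log₂
fold-changes of stage means; raw p-values are reported by default with
Benjamini–Hochberg available behind a flag, since the screening cut-off
(|log₂FC| ≥ 1, p < 0.05) is exploratory rather than confirmatory.

GPR evaluation maps AND → min and OR → max over scored children; a gene
without data is ignored inside an operator as long as a sibling is scored,
and a reaction is unscored only when no leaf has data.  This keeps the
"no expression data" class well defined, which the extraction methods need
(unscored reactions are never core for FASTCORE and carry weight −2 in
INIT).  The mapping is monotone in every gene value.

## Context-specific extraction

Thresholds are always statistics of the supplied reaction-expression array —
the array minimum, the smallest value of the top decile (ceiling count), or
mean ± sd — never constants.  The minimum activation flux ε for the integer
programs is 10⁻³, three orders above the activity tolerance, so "active"
and "numerically nonzero" cannot be confused.

* **iMAT** maximises the count of high-expression reactions at |v| ≥ ε plus
  low-expression reactions at zero, as a MILP solved with HiGHS
  (deterministic).  The returned model keeps every reaction that is active
  or *can be made* active in some optimum-attaining solution (an FVA pass
  with the indicator count pinned at its optimum), then reduces to the
  flux-consistent subnetwork.  A reaction whose bounds exclude zero can
  never be counted as "off" — the formulation respects the original bounds.
* **FASTCORE** implements the classic LP7/LP10 sequence with bound flipping
  for reversible core reactions and the usual 10⁵ scaling in the sparse
  support step; the output always contains the core.
* **INIT** maximises the summed reaction weights, 5·log₂(exp/threshold)
  (−2 when unscored), as a MILP in which an excluded reaction carries zero
  flux and an included one must reach |v| ≥ ε *in a single steady-state
  witness vector* — a slightly stronger reading than per-reaction
  activability that makes post-hoc inconsistency impossible by
  construction.

Tie-breaking among alternative optima is delegated to the deterministic
solver; the published method does not specify which optimal model to keep.

## Flux states

The steady-state polytope is sampled with cobra's artificial-centering
hit-and-run sampler; the default budget is 2 × number of reactions.  The
chain is thinned by 10: at thinning 1, consecutive hit-and-run points are
strongly autocorrelated and small sample sets never visit the extreme flux
splits that the subsequent max-correlation selection is designed to find.
Burn-in beyond cobra's internal centering is unnecessary at these budgets.
Every sample is validated against |S·v| ≤ 10⁻⁶ and the bounds; escaped
points are redrawn.  Sampling is bit-reproducible for a fixed seed.

The stage flux state is the sample with maximal Pearson correlation between
flux *magnitudes* and the reaction-expression array (ties → lowest index).
Whether signed or absolute fluxes should be correlated is not determined by
the method's description; absolute is the default and signed is a flag,
since expression is a proxy for enzyme capacity, which is unsigned.

A deterministic alternative, `lp_flux_state`, returns the expression-aligned
extreme point: the LP maximising the z-scored-expression-weighted sum of
fluxes.  It is the limit the max-correlation selection gravitates towards as
the sample budget grows, costs one LP, and is seed-free.

## Functionality score and its significance

The biomass reaction is removed, one irreversible sink per growth-essential
metabolite is added, and the score counts sinks whose FBA maximum exceeds
10⁻⁶.  Significance compares against random same-size flux-consistent
submodels of the parent: reactions are removed uniformly at random down to
the context size, consistency is restored, and removed reactions are
greedily re-added while the model is more than 2% under size; the sink set
is part of every scored model.  The p-value is the strict fraction
`count(random score > observed)/iterations`, as published — p = 0 is
attainable and no +1 correction is applied.  `draw_random_context` exposes
the same null draw so calibration can be checked (a context drawn from the
null receives an unremarkable p).

## Perturbation detection

On the reactions common to both stage models, magnitudes are floored at the
activity tolerance and the ratio tested against the inclusive two-fold
cut-off in either direction; a sign flip with both magnitudes above the
floor is also perturbed (flux reversal is a real rerouting even at equal
magnitude — a documented choice, as the published text is silent).
Subsystem enrichment is the hypergeometric upper tail over the common-
reaction universe, raw p < 0.05 by default, BH behind a flag.

## Module search

Candidate evaluation — re-estimating the later-stage flux state after each
trial clamp and correlating it with the initial-stage state over the
perturbed set — is the cost centre: the greedy search evaluates hundreds of
candidates.  Two evaluators share one interface:

* the **LP evaluator** (default in the test and acceptance harnesses):
  deterministic, one LP per candidate;
* the **ACHR evaluator**: the sampling protocol of the stage states, with a
  configurable point budget and seeds derived from (base seed, evaluation
  counter).

Infeasible clamps are rejected outright (correlation −∞), not treated as
zero gain.  Candidates are attempted in single-scan rank order, fixed across
levels; a clamp is kept only for a gain ≥ 0.001 (internal cut-off) and
levels repeat until the inter-level gain is < 0.01 (external cut-off) —
the published calibration of these two values.  Twenty strategies are
seeded from the top twenty single modulations; the published account shows
twenty strategies without describing how they were diversified, so seeding
from the single-modulation ranking is this package's documented choice.
Within a strategy the correlation trace is non-decreasing by construction,
and accepted clamps commute (re-applying them in any order reproduces the
final correlation).

The targetability of a strategy is the percentage of its catalysing genes
(union over GPR rules) that are non-essential; a strategy with no
gene-associated reaction has an undefined score.

## Intervention screens

E-flux scales each scored reaction's upper bound to
`b_max · exp / max(exp)` with `b_max = 1000` (the model's default bound
scale) — the published account leaves f(expression) unspecified, so linear
scaling to the per-sample maximum is the package's choice; reversible
reactions get the symmetric lower bound, irreversible ones lb = 0.  The
normal-tissue panel is quantile-normalised (average-rank reference).  A gene
is non-essential when its knockout leaves the growth rate unchanged
(ratio 1 within 10⁻⁶) in at least ⌈samples/3⌉ models; bound shrinkage can
never raise an LP maximum, so ratios are ≤ 1.

Knockout disables reactions whose GPR evaluates false without the gene
(boolean semantics: complexes die, isozymes survive).  Drug inhibition
instead scales the bounds of *every* reaction whose GPR mentions a target —
membership, not boolean, semantics: partial inhibition must dampen
isozyme-backed reactions too.  The two rules agree in the 100%-inhibition
limit exactly on single-gene GPRs.  Screens report the post-intervention
correlation with the initial stage over the perturbed set and its log₂
fold-change against the transition baseline; correlations are floored at
0.01 before the ratio, because the baseline of a strongly shifted
transition is near zero or negative and the published fold-change filter
(log₂FC > 2) is otherwise undefined.  The inhibition scan covers 10%–100%
in 10% steps and flags the smallest level within 0.01 of the curve's
plateau.  The IC50 z-score uses the standard population σ denominator; the
variance-denominator variant is available for audit.

## The synthetic study

The generator emulates the full input bundle at toy scale: a BiGG-style
JSON model, a three-stage × three-replicate abundance TSV, drug and IC50
tables, and a normal-tissue panel.  The network routes a fixed glucose
uptake (10 mmol·gDW⁻¹·h⁻¹) through `n_core` serial segments, each
catalysable by a baseline enzyme P_i or an alternative enzyme Q_i with
capacity 8; a linear biomass chain and constitutive fixed-flux side
branches complete the network (five subsystems, each with reversible and
irreversible members, isozyme and complex GPRs, carbon formulas
throughout).  Deliberate structural choices:

* the planted module is `n_core` *independent* segment bypasses, so
  recovering it genuinely requires every member (a serial module would
  collapse to a single representative under the greedy acceptance rule);
* Q capacity (8) sits below the throughput (10), so 50% bound inhibition
  re-routes the majority of flux — a drug effect that large default bounds
  would swallow;
* no reversible reaction sits inside a parallel pair, so extreme flux
  states cannot inflate futile cycles;
* the side branches carry fixed flux, concentrating the stage contrast on
  the planted module;
* P_i and Q_i share a baseline abundance draw, so the planted contrast is
  the planted fold itself rather than an accident of absolute abundance.

Expression baselines are log-normal (μ = ln 100, σ = 1) with multiplicative
noise at CV 0.1; planted genes rise and counter genes fall by the effect
size (default 4) at each consecutive transition, with a half-step offset so
the planted/counter ratio already equals the effect at the middle stage.
Missingness (≈5%) is missing-at-random with a low-abundance bias, plus
crafted extra proteins exercising the replicate-filter edge cases.  The
five essential genes are the sole catalysts of the uptake–hub–biomass
chain.

What passing on this generator does **not** show: the toy polytope is
low-dimensional, expression noise is uncorrelated across genes, the module
is cleanly separable, and thermodynamic (loop) constraints are absent —
results on a genome-scale reconstruction with real proteomics will be
noisier in every step, particularly the sampled flux states.

## Problem sizes

Tests and the acceptance script run the default generator (26 reactions,
21 genes), ten-seed recovery batteries, 200-draw randomisation p-values and
a 400-point sampler for the uniformity check — sizes chosen so the full
analysis re-runs in well under a minute while every algorithmic branch is
exercised.

## Known limitations

* The greedy module search is order-dependent by design (it reproduces the
  published procedure); it is not an optimal-subset search.
* iMAT's "activatable in the optimum" reduction solves two MILPs per
  reaction and is intended for context models up to a few hundred
  reactions; genome-scale use should replace it with a single-solution
  reduction.
* No loopless-flux correction is applied anywhere (the published method
  uses none); thermodynamically infeasible cycles are instead avoided
  structurally in the synthetic generator and capped by finite bounds in
  real models.
* The ACHR sampler inherits cobra's limitation on problems with very few
  degrees of freedom (a near-point polytope cannot be sampled).
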
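# Methods

This note records the models the package implements, the assumptions
and numerical choices behind them, what the synthetic-data generators
do and do not emulate, and the known limitations. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Chronograms and lineage-through-time machinery

A chronogram is a rooted tree with branch lengths in Myr; node ages in
Ma before present are always derived explicitly as `root_age - depth`
(present = 0). Ultrametricity is enforced within a *relative* tolerance
of 1e-6 of the root age; trees failing it are rejected by every
operation that uses branch lengths (ages, LTT, truncation,
diversification, DEC) and accepted with a warning by parsimony, which
only reads the topology. Polytomies are likewise accepted by parsimony
(multifurcating Sankoff) and rejected by the birth–death machinery.
Negative branch lengths are always rejected; zero-length terminal
branches are fine.

The LTT count at age t is 1 + (number of branching events strictly
older than t), so a query exactly at an event age returns the
older-side count; `truncate_at_age` uses the same convention, which
makes "tip count of the truncated tree = LTT count at the cutoff" an
exact identity rather than an approximate one. A truncated tree's tips
end on the cutoff line; the returned object carries `age_offset` so
absolute ages can be recovered.

Newick I/O is delegated to dendropy for parsing (with our own
validation layered on) and to a small writer that prints lengths via
`repr`, so a write/parse cycle reproduces topology and lengths to
better than 1e-9 (tested on simulated trees and random topologies).

## Supermatrix occupancy

A taxon *has* a locus iff its partition slice contains at least one
non-missing character. The missing alphabet defaults to `- ? N n X x`;
IUPAC ambiguity codes count as data. This choice is configurable
because published completeness numbers rarely state it; with aggregate
counts as inputs (`summary_from_counts`) the question does not arise.
Percentages are kept at full precision internally and rounded half-up
to one decimal only at reporting (`round1`), matching how such tables
are printed.

Partition files use the RAxML dialect `DNA, name = start-end` with
1-based inclusive coordinates, converted internally to 0-based
half-open; intervals must tile the alignment without overlap.

## MAC parsimony

Ancestral ranges are non-empty area sets of cardinality at most
`max_range_size` (2 for the primate system: almost no extant primate
occupies more than two of Africa / Madagascar / Asia / New World). The
transition cost is the symmetric difference |S △ T| — each area gained
or lost counts one change — which makes a switch between two singleton
ranges cost 2 (a loss plus a gain). Consequently, with
`max_range_size = 1` the MAC minimum equals exactly twice the Fitch
change count; the tests assert that factor-2 identity against an
independent Fitch implementation.

The minimum total change count comes from standard Sankoff DP
(up-pass), per-node MPR state sets from an up+down pass, and the exact
(min, max) decomposition of changes into gains vs losses across *all*
most-parsimonious reconstructions from an augmented DP whose per-node
state is a map cost → (min gains, max gains), pruned at the global
minimum. No sampling of MPRs is involved; the extremes are exact, and
on trees of up to 8 tips they are verified against vectorized
exhaustive enumeration of every internal-state assignment.

## DEC likelihood

Anagenesis: a range S gains area a ∉ S at rate d·|S| (uniform
dispersal multipliers — every occupied area is an equally good source)
and loses each a ∈ S at rate e; a singleton extirpated to the empty
(null) range stays there. Ranges above `max_range_size` are excluded
from the state space. Cladogenesis: a singleton parent range is
inherited identically by both daughters; a two-area parent {a,b}
resolves into one of six scenarios — ({a},{b}), ({b},{a}), ({a},{a,b}),
({a,b},{a}), ({b},{a,b}), ({a,b},{b}) — with equal weight 1/6 (the
Lagrange convention; nothing in the data here can distinguish the
weightings, so they are fixed and documented rather than estimated).
The root prior is uniform over the non-null ranges; since the null
range is excluded from the prior, no additional conditioning step is
applied (the alternative renormalization would only rescale by a
constant here).

The pruning pass propagates conditional likelihood vectors with
per-branch transition matrices. For speed the generator matrix is
diagonalized once per parameter value and propagators are built as
V·diag(e^{wt})·V⁻¹, with an automatic fall back to
scaling-and-squaring `expm` whenever the eigendecomposition fails to
reproduce `expm` on the longest branch to 1e-10 (defective or
ill-conditioned Q). Zero-length branches yield the identity exactly.
Per-node rescaling keeps the pass in floating range; data of
probability zero (e.g. tips in three different areas with d = 0)
return −inf rather than raising. The implementation is verified on
two-tip trees against direct ODE integration of the same generator
(`solve_ivp` at rtol 1e-10), agreeing to better than 1e-6.

`dec_fit` maximizes over (log d, log e) with multi-start L-BFGS-B in
bounds d ∈ [1e-6, 10], e ∈ [1e-8, 10] per Myr; a 20×20 log-spaced grid
scan is available as a cross-check and as the fallback on
non-convergence. `dec_node_ranges` re-computes the global likelihood
with each candidate state clamped at a node; the exact identity
logsumexp(clamped over states) = unclamped log-likelihood is what the
tests assert (the best clamped state equals the unclamped value only
when that state carries all the posterior mass). Candidates within 2
log-units (configurable) are reported, sorted by Δ lnL with ties broken
by state order (cardinality, then bitmask) — dispersal-event arrows
depend on this tie-break, so it is fixed and documented.

`count_dispersals` records one event per area present in a child
node's range and absent from its parent's; range contractions at
cladogenesis are inheritance, not dispersal. This node-level
differencing cannot see an area lost at cladogenesis and regained
along the same branch; against the simulator's event log the counted
events are therefore a subset of the true dispersals, exact per branch
relative to the *inherited* start range (both properties tested).

### Identifiability of e

The extirpation rate is weakly identified: a single-area tip under a
two-area ancestor is explained equally well by cladogenetic splitting
as by extirpation, and lineages whose range actually dies out leave no
extant tip to observe. The generator, which resimulates any branch
that hits the null range (the extant tree is given, so its lineages
by construction did not die out), reinforces this: the fitted ê sits
at the zero boundary in essentially every replicate even when the
generating e is positive, while d̂ is recovered well (median within a
few percent of truth at ~200 tips). The profile over e does have an
interior optimum when extirpation strongly shapes the data, so the
machinery is sound — the parameter, not the code, is the problem.
Reported ê values should be treated as lower bounds near zero, as is
the common experience with this model.

## Piecewise birth–death shift detection

Rates are constant within epochs delimited by shift ages (epoch 0
youngest); each extant species is sampled with probability ρ at the
present only (per-epoch sampling is out of scope). Writing E(t) for
the probability that a lineage at age t leaves no sampled descendant
and u = 1 − E, each epoch has the closed forms

    1/u(t) = λ/r + (1/u(t₀) − λ/r) e^{−r(t−t₀)},  r = λ − μ  (r → 0 limit: 1/u(t) = 1/u(t₀) + λ(t−t₀))
    log q(t) = log q(t₀) + 2[log u(t) − log u(t₀)] − r(t−t₀)

glued continuously across shifts from E(0) = 1 − ρ, q(0) = 1. The
log-likelihood of the branching ages x₁ > x₂ ≥ … ≥ x_{n−1}, dropping
labeling constants and conditioning on survival of both lineages of
the root split (no root edge — the data begin at the root split), is

    log L = 2 log q(x₁) − 2 log u(x₁) + Σ_{i≥2}[log λ(x_i) + log q(x_i)] + n log ρ.

At k = 0 this equals the textbook constant-rate reconstructed-process
likelihood, checked against an independently coded closed form (via
the sampling identity (λ, μ, ρ) ≍ (λρ, μ − λ(1−ρ), 1)) to 1e-9 on 100
random draws, and its μ = 0, ρ = 1 maximum matches the analytic Yule
estimator λ̂ = (n−2)/(2x₁ + Σ_{i≥2} x_i) to 1e-6.

Fitting: shift ages live on a grid (default 0.1 Myr from 0.5 Ma to
root − 0.5 Ma; detected times are therefore grid-quantized, and the
replicated experiments in the tests use a 0.5-Myr grid to keep 50-fold
replication affordable). Epoch rates are optimized by bounded
L-BFGS-B in log space (λ ∈ [1e-5, 10], μ ∈ [1e-9, 10]) from several
starts, with warm starts carried along the grid. For k ≥ 2 the search
is greedy-sequential: previously accepted shift ages are held at their
fitted grid values while the new shift is scanned and all rates are
re-optimized jointly — a full joint grid over shift-time combinations
grows combinatorially and the greedy placement recovers nested
shift structures well in practice.

The extinction rate can be pinned per fit (`fix_mu`), giving a
pure-birth shift model. This matters for shift-age localization: with
μ free, a misplaced shift can partly mimic the true signal through
inflated extinction in the older epoch, so the profile over shift age
develops spurious local maxima; when extinction is known to be
negligible, fixing μ = 0 sharpens localization considerably (the
recovery experiment in the tests is run both ways; the matched
pure-birth fit recovers a planted 8-Ma shift within ±1.5 Myr in ≳90%
of replicates, the free-μ fit in ~70%). The grid scan itself carries
warm starts from neighboring grid points (profile continuity) and
re-polishes the winning point with the full multi-start set.

Model selection is sequential: accept k over k−1 when
2·(lnL_k − lnL_{k−1}) exceeds the critical value, stopping at the
first failure. The default critical value is the χ²₃ 0.05 quantile
(three added parameters), but because the grid-maximized statistic is
not χ²-distributed the honest route is `calibrate_type1`: simulate
constant-rate trees conditioned on the observed tip count and root age
(rejection sampling, exact for n ≤ 50, ±10% above), fit k = 0 and
k = 1 to each, and take the empirical 95th percentile of the statistic
(typically above the χ² value, e.g. ≈ 9.4 vs 7.8 in the configurations
tested — but no direction is assumed). The calibration needs null
rates; by default a pure-birth rate matched to (n, root age, ρ) is
used, and both can be supplied. Shifts are labeled increase/decrease
by the sign of the change in net rate r = λ − μ toward the present.

`constrained_shift_test` restricts the one-shift grid to a window
(e.g. 33.4–34.4 Ma around the Eocene–Oligocene turnover) and compares
against the one-rate model; Δ lnL is clipped at 0 (the models are
nested) and a point window degenerates exactly to a fixed-shift-time
fit.

## Fossil diversity

Occurrence pruning follows the species-level rule: binomials are kept
(pooled per species across records); a genus represented only by
indeterminate material collapses to one pseudo-species spanning its
records; a genus with both drops the indeterminate ones. Pruning is
idempotent. Range-through standing diversity counts every taxon whose
first–last interval spans the query age, boundaries inclusive (a range
is the complete interval between first and last occurrence).

Interval net rates are ln(N_end/N_start)/Δt per lineage per Myr — the
estimator that telescopes exactly (exp(Σ rᵢΔtᵢ)·N₀ returns the final
count); an arithmetic-difference variant is deliberately not the
default. Timetree rates use the LTT count at each boundary; intervals
reaching above the root are reported missing (NaN) and dropped
pairwise before correlation. Rate series are compared with Pearson's r
(Spearman available). Recomputing the published primate comparison
from the shipped 11-interval table gives r = 0.248 (fossil vs
autocorrelated-rates/hard-bounds timetree) and 0.272 (vs soft bounds):
the printed inputs carry 3 significant figures, which accounts for the
~1e-3 wobble against the published 0.249/0.272.

## Calibration bounds

The 14 Cenozoic chronologic units (Pleistocene … early Paleocene, with
the Miocene and Eocene split into the conventional stage groupings)
ship with Gradstein & Ogg stage-boundary ages and are fully editable —
the rules, not the numbers, are the contribution. Stratigraphic
bounding starts at the unit containing the oldest clade fossil and
walks rootward until **two successive** fossil-free units have passed;
the bound is the old boundary of the second. "Successive" is strict:
an occupied unit resets the barren run. Units strictly older than the
oldest-fossil unit are what the walk inspects (a fossil at a unit base
still occupies that unit). If fewer than two barren units remain the
oldest unit's old boundary is returned with a `truncated` flag.
Removing occurrences can only shrink the occupied set, so the bound is
monotone non-increasing under record removal (tested). Phylogenetic
bracketing takes the oldest stem fossil on the branches subtending the
node and its parent (two nodes rootward); deeper fossils are out of
bracket and yield a missing value. The phylogenetic-uncertainty
contribution is a user-supplied age — no formula for it exists — and
enters only through the final max. A bound with max ≤ min is an error
naming the clade.

Violation auditing measures against the bound itself (not credibility
intervals): magnitude = min − age for minimum violations, age − max
for maximum violations; the mean is over violations only, and an
estimate exactly on a bound is compliant. The six published soft-bound
checks of the primate timetables reproduce a mean violation of 3.6 Ma.

## Synthetic data: what it emulates, what it does not

All generators take a seed (or a Generator) and draw from a stream
keyed by a fixed per-generator id, so outputs are bit-identical under
a fixed seed and adding a generator never perturbs existing fixtures.

* `sim_bd_tree` simulates forward in time from the two root-split
  lineages under piecewise-constant (λ, μ), applies ρ-sampling at the
  present, and prunes to the reconstructed tree of sampled tips;
  conditioning on tip count (for type-I calibration) is by rejection,
  not by the backward constrained algorithm. The event log carries the
  true branching ages and every lineage segment's (origin, end).
* `sim_dec_tips` runs a Gillespie walk of the DEC generator along each
  branch and draws cladogenetic scenarios uniformly; branches hitting
  the null range are resimulated (the extant tree is fixed), which is
  exactly the conditioning discussed under "Identifiability of e".
* `sim_species_durations` / `sim_fossil_ranges` produce true species
  durations (uniform origins, exponential lifetimes, optional
  extinction pulse that truncates survivors with a given probability)
  and observed ranges eroded at both ends by exponential preservation
  noise, with optional genus-indeterminate records injected for the
  pruning rule to remove.
* `sim_occupancy_matrix` plants a Bernoulli presence mask (with an
  optional high-completeness exemplar backbone, the structure real
  supermatrices have) and writes FASTA + partition text that the audit
  module reads back, recovering the mask exactly.

None of the generators emulate real sequence evolution, fossil
preservation biases that vary in time or space, gene-tree discordance,
or taxonomy-induced correlations between sampling and clade identity.
Green tests therefore certify the estimators against their own
generating models and against independent oracles — not that any
particular empirical data set satisfies those models.

## Problem sizes used in the checked experiments

The replicated experiments run at: MAC vs brute force, 51 trees of 4–8
tips; DEC ODE oracle, 20 two-tip draws; DEC rate recovery, 10
conditioned ~200-tip trees; shift-time recovery, 50 trees of ~300 tips
(λ 0.1 → 0.3 at 8 Ma, 0.5-Myr grid, ±1.5 Myr criterion); type-I
calibration, 200 calibration + 500 evaluation trees of 40 tips; the
full-scale stand-in, the median fitted shift age over 5 chronograms of
~250–600 sampled tips at crown age 67.8 Ma with ρ = 0.816 (the median
suppresses the stand-in's draw-to-draw noise, which the original
single-tree analysis did not have). These sizes were chosen to make each
experiment's Monte-Carlo error small relative to the property being
asserted while keeping the whole suite runnable on one CPU.

## Known limitations

* No founder-event (jump) cladogenesis, time-stratified dispersal
  matrices, or Bayesian range reconstruction in the DEC module.
* No per-epoch sampling fractions, mass-extinction events, or
  diversity-dependent rates in the shift module; the k ≥ 2 search is
  greedy, so pathological shift configurations could in principle be
  missed.
* ê in DEC is biased toward zero (see above); interpret accordingly.
* Fossil interval rates are a net-rate estimator only; origination and
  extinction are not decomposed, and no sampling standardization
  (rarefaction/SQS) is applied.
* The calibration module takes the set of calibrated nodes as input;
  choosing them is a scientific decision outside its scope.
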
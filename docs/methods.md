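# Methods

This note records the models implemented in `biogeodiva`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions a maintainer would want
written down.

## Tree model

`DatedTree` is a strictly bifurcating rooted tree with branch durations in
Myr.  Node ages in Ma are derived as (maximum root-to-tip path) −
(root-to-node path); tips must sit at age 0 within a relative tolerance of
1e-6 of tree height (dating software emits rounded branch lengths, so exact
equality is not expected).  Polytomies are rejected with a validation error
rather than auto-resolved: the dispersal–vicariance model is defined on
bifurcations, and silent resolution would manufacture cladogenetic events;
callers can pre-resolve if they accept that.  Clades are identified across
topologies by the sorted tuple of subtended tip labels (`CladeKey`), which
is what makes "the same clade in all topologies" well defined when tree
shapes differ.  Posterior tree samples discard a 25% burn-in by count
(rounded down) by default, matching the usual MCMC protocol.

Topology discordance (`discordant_taxa`) is a greedy approximation to the
taxon lists produced by Disagree-style tree comparison: repeatedly remove
the single taxon whose removal maximally shrinks the symmetric difference
of the two clade sets, ties broken alphabetically, until the difference is
empty.  Greedy search is not guaranteed minimal; the suite checks minimality
exhaustively on small cases and reconciliation on random pairs.

## DIVA and S-DIVA

Costs: vicariant splits (two disjoint non-empty subsets of the parent
range) and single-area duplications are free; each area gained on a branch
(dispersal) and each area lost (local extinction) costs 1.  The
implementation is a two-pass dynamic programme over all candidate ranges:
an upward pass `up[v][R]` (minimal subtree cost given node v holds R) and a
downward pass `down[v][R]` (minimal cost of the rest of the tree), so the
per-node optimal set is `{R : up+down = global min}` — every range
attainable in *some* globally optimal history, weighted uniformly.  No
single arbitrary optimum is ever reported.

Exact mode enumerates all non-empty subsets and is capped at 8 areas (the
split enumeration grows as 3ⁿ); beyond that, candidate ranges are
restricted to unions of observed tip ranges and a warning is emitted.
The maximum ancestral range size defaults to 12 (i.e. unconstrained for
the default alphabet).  S-DIVA averages each tree's uniform tie-weights
per clade across a tree sample; clades absent from some trees are reported
with their occupancy fraction rather than silently renormalised.

The brute-force oracle used in the tests enumerates every assignment of
ranges to internal nodes and every split per node on `frozenset`s, sharing
no code with the bitmask DP; the two agree on minimal cost and optimal
root-range sets on hundreds of random instances.

## Bayesian binary MCMC (BBM)

Each area is an independent two-state (absent/present) CTMC along the tree.
The "empirical" parameterisation sets the stationary presence frequency of
area *a* to the observed fraction of tips occupying it, clamped to
[0.05, 0.95] to avoid degenerate likelihoods (areas occupied by no tip or
by all tips trigger a logged warning), and scales the rate so one change
per area is expected over one tree height — an F81-like reading of an
"empirical model" option that is named in common software but not defined
mathematically.  Both the frequencies and the rates can be overridden with
known values (`stationary_freqs=`, `rates=`), which is what the
parameter-recovery suites do, since they test the sampler rather than the
rate heuristic.

Sampling is single-site Gibbs over the free internal-node presence bits,
one full sweep (fresh random node order) per generation, with transition
probabilities P(t) = π + (δ − π)e^(−rt) precomputed per branch.  Root
priors: *null* samples the root like any node with the stationary prior;
*wide* fixes the root to the full alphabet; *custom* fixes a user-supplied
range (the software options this mirrors do not document what any
particular "custom" distribution contained, so explicit input is
required).  Two independent runs of 50,000 generations each discard a 25%
burn-in and are pooled; the maximum between-run difference in any per-node
marginal is reported as a convergence diagnostic.  The sweep kernel is
numba-compiled; all seeds derive from one master seed, so runs are exactly
reproducible.  Correctness is cross-checked in the tests against the exact
posterior computed by Felsenstein peeling (agreement to ~2 decimal places
at default chain lengths).

Per-node range weights are the product-Bernoulli distribution implied by
the pooled marginals, restricted to non-empty ranges and renormalised; the
root additionally carries the *joint* pattern posterior tallied directly
from the samples, which is what recovery checks use (the product form
ignores the correlation the tree induces between areas).

## Event calling and route strings

Per-node events are called from modal ranges (highest weight, smallest
bitmask on ties, for determinism).  For a widespread modal parent P the
two *inherited* subsets are inferred by minimal-event reasoning: the
ordered disjoint bipartition of P that reaches the modal child ranges with
the fewest subsequent gains/losses is compared with full inheritance
(both daughters start at P), and vicariance is called when the bipartition
is strictly cheaper.  A naive rule that intersects child ranges with P
was tried first and discarded: as soon as a daughter branch re-gains an
area from the sibling's half — which happens routinely when dispersal
continues after a split — the intersections overlap and genuine vicariance
becomes undetectable.  Routes serialise as
`<parent> ( "|" left "^" right | "->" gained )*` (e.g. `AB|A^B->C`) and
the grammar round-trips exactly.

Consensus filtering keeps a clade when (1) it is called vicariant in at
least 50% (inclusive) of the reconstruction grid — counted over the full
grid by default; a per-topology mode is available since the criterion
could also be read per topology — and (2) the clade occurs in every
supplied topology.

## HPD intervals and congruence testing

The 95% HPD is the shortest window over the sorted samples spanning
k = ⌈0.95·n⌉ − 1 order statistics, ties resolved toward the smaller lower
bound.  Geological windows are entered older-bound-first as printed
(either order is normalised) and intersected as closed intervals — a
shared endpoint counts as overlap, which is conservative toward
non-rejection.

The default decision rule, `all-runs-overlap`, rejects a window iff it is
disjoint from the node-age interval in at least one dating analysis.  The
choice among plausible rules was fixed by requiring that the packaged
hypothesis-table transcription reproduce its recorded decision column
exactly (14/14): a single-interval overlap rule cannot reproduce the
recorded Acre-system rejection, whereas disjoint-in-≥1-analysis reproduces
every row.  `any-run-overlap` and `mean-in-window` remain selectable, and
the rule in force is recorded in every report.  One hypothesis class is
*biotic* rather than geological (dispersal with an ecologically associated
clade); it is tested identically but excluded from the geological tally
(13 geological windows across 14 table rows).  No multiple-testing
correction is applied, and reports say so.

The calibration table carries one prior per fossil with per-configuration
membership (B1 = the single deep root calibration, B2 = six, B3 = seven);
one fossil appears with two distribution variants (normal in B3,
exponential with a 25 Ma hard minimum in B2), stored as two rows.  Decimal
commas in the source ("10,5", "32,5") are normalised to decimal points.

## Precision regression

Ordinary least squares of 95%-interval width *w* on mean node age *m*,
per dating analysis, fitted only on the nodes present in every analysis so
slopes are comparable (dropped nodes trigger a warning; fewer than three
shared nodes is an error).  Implemented with the closed-form least-squares
solve; the suite cross-checks slope, intercept and residual standard error
against statsmodels OLS.

## Synthetic data: what it emulates, what it does not

`SimulationConfig` defaults: 20 tips, birth 0.15 / death 0.05 per Myr
(yielding crown ages of a few tens of Myr at that tip count), a 3-area
alphabet, gain = loss = 0.01 per Myr per area (modest range turnover:
roughly 0.2–0.6 expected changes per area along a root-to-tip path),
1,000 pseudo-posterior samples per node, lognormal noise scales
B1 = 0.30 > B2 = 0.20 > B3 = 0.12, seed mandatory.

* **Trees** come from forward birth–death simulation stopped when the
  extant count first reaches `n_tips` (plus one further waiting time so
  the final sisters are not zero-length), extinct subtrees pruned,
  resampled up to 1,000 times on total extinction.  This is approximate
  conditioning — chosen for simplicity — not an exact sample from the
  conditioned process.
* **Ranges** evolve per-area independently along branches; at implanted
  nodes the parent range is split uniformly at random into two disjoint
  non-empty halves.  Lineages are conditioned never to go range-extinct
  (empty results are re-drawn and counted).  If evolution shrinks an
  implanted node's range to one area, the node gains one random area just
  before the split (recorded in the truth tables as a forced expansion);
  a *configured* impossibility — implanting at the root while forcing a
  single-area root range — raises instead.
* **Pseudo-posteriors** for a node of true age *a* are
  LogNormal(ln a − σ²/2, σ) draws, so their mean is *a* and their spread
  is proportional to a·σ: interval widths grow with node age and shrink
  from B1 to B3, reproducing the qualitative width-vs-age structure of
  nested calibration analyses without re-running any dating MCMC.

What passing tests therefore show: the pipeline recovers implanted
cladogenetic structure and makes calibrated interval decisions *under its
own model assumptions*.  What they do not show: robustness to correlated
range evolution between areas, to founder-event speciation, to
non-ultrametric input error, or to dating posteriors whose noise is not
age-proportional — none of which the generator produces.

The consensus-recovery suite uses a 6-area alphabet rather than the 3-area
default: three nested vicariant splits cannot coexist in three areas
(each split strictly shrinks the range, so a third nested split would
always require a forced expansion first), and the suite implants
vicariance at the three oldest nodes.

## Problem sizes and numerical choices

The pytest suite runs the recovery studies at 20 seeded replicates with
50,000-generation chains; `scripts/acceptance.py` re-derives the same
quantities at reduced replicate counts (100 DIVA oracle instances, 300 HPD
coverage replicates, 10 BBM recovery replicates, 8 consensus replicates)
and records the size next to every number it reports.  Weight
normalisations are asserted to 1e-9; DIVA optimality comparisons use an
absolute slack of 1e-9 on integer costs; route-modal ties break toward the
smallest bitmask; all Monte-Carlo assertions state their tolerance
inline.

## Known limitations

* The BBM root-pattern recovery study is intrinsically hard under the
  default turnover: with gain = loss = 0.01/Myr the *exact* posterior of
  the true root pattern (computed by peeling) exceeds 0.8 in only ~70% of
  random replicates — truth often flips along the long root-adjacent
  branches, which no sampler can undo.  The suite reports this honestly
  rather than easing the conditions.
* DIVA exact mode is capped at 8 areas; the >8-area fallback restricts
  candidates to unions of observed tip ranges and can in principle miss
  optima involving unobserved areas.
* The greedy discordance search is an approximation; minimality is only
  guaranteed on the small cases the tests enumerate.
* BBM range weights away from the root assume per-area independence of
  the marginals.
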
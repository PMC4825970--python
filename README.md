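# biogeodiva

Event-based historical biogeography on dated phylogenies: ancestral-range
reconstruction, consensus vicariance calling, and temporal-congruence
testing of geological events against node ages.

## Who this is for

Systematists and biogeographers who have (a) one or more rooted, ultrametric,
fossil-calibrated trees with branch lengths in Myr, and (b) a taxon × area
presence/absence matrix, and want to answer: *which splits in this phylogeny
were vicariant, and could a dated geological or climatic event have caused
them?*  The package was built around a Neotropical insect radiation coded on
twelve biogeographic areas (A–L, Mexican Transition Zone through North
America) with three nested Bayesian dating analyses (B1/B2/B3, using one,
six and seven fossil calibrations), but every stage is generic.

## What it computes

**Ancestral ranges.** Two reconstructions of the range of each ancestor:

* **DIVA / S-DIVA** — exact event parsimony.  A range R ⊆ areas splits at a
  node by free vicariance into disjoint subsets (or free duplication when
  |R| = 1); along a branch each area gained (dispersal) or lost (local
  extinction) costs 1.  `diva_optimize` returns, per node, every range
  attainable in a globally minimal-cost history (uniform tie weights) via
  bottom-up/top-down dynamic programming; `sdiva` averages those weights
  over a posterior sample of trees.
* **BBM** — Bayesian binary MCMC.  Each area is an independent two-state
  Markov chain along the tree (stationary presence frequency π̂ₐ estimated
  from the tips, rate scaled to one expected change per tree height);
  ancestral presence bits are Gibbs-sampled under a *null* (stationary),
  *wide* (root = all areas) or *custom* root prior, two pooled runs of
  50,000 sweeps with 25% burn-in each.

**Vicariance consensus.** Per-node events (vicariance `|`, dispersal `->`,
expansion `^`, extinction, duplication) are called from modal ranges by
minimal-event reasoning and serialised as route strings such as
`AB|A^B->C`.  A clade becomes a consensus vicariance call when it is
vicariant in ≥ 50% of a methods × topologies reconstruction grid *and*
appears as a clade in every topology.

**Temporal congruence.** For each candidate event the 95% HPD interval of
the clade's age (shortest window over the posterior samples, per dating
analysis) is intersected with the event's geological window [younger,
older] Ma.  Under the default `all-runs-overlap` rule the null hypothesis
("this event drove the split") is **rejected** iff the window is disjoint
from the interval in at least one analysis.  No multiple-testing
correction is applied.

**Calibration sensitivity.** Per analysis, OLS of 95%-interval width *w*
on mean node age *m* — the slope measures how dating uncertainty grows
with age, and slopes shrink as calibrations are added.

A seeded synthetic-data module (`simulate_dated_tree`,
`simulate_range_evolution`, `simulate_age_posteriors`) generates birth–death
trees, range evolution with vicariance implanted at chosen nodes, and
pseudo-posterior node ages whose spread grows with age and shrinks from B1
to B3 — every recovery property in the test suite runs against this ground
truth.

## Worked example

The packaged transcription of the hypothesis table (11 cladogenetic events
× candidate windows, with the 95% intervals of the three dating analyses)
runs through the congruence stage in well under a second:

```python
import biogeodiva as bg

rows = bg.load_fixture("table3")
report = bg.run_hypothesis_table(rows, rule="all-runs-overlap")
```

prints, when summarised:

```
rows: 14 | rejected: 2 | cladogenetic events: 11 | geological hypotheses: 13 | mismatches: 0
  rejected: T. maculata / infestans group  vs  Acre System (10.0-7.0 Ma)  flags={'B1': True, 'B2': False, 'B3': True}
  rejected: T. bruneri / megistus group  vs  GAARlandia (35.0-33.0 Ma)  flags={'B1': False, 'B2': False, 'B3': False}
```

Reading: of 13 geological windows tested (the biotic "Hitchhiking"
hypothesis is tested but tallied separately), only two are incompatible
with the node ages — the Acre system misses the B2 interval entirely, and
the 35–33 Ma GAARlandia land bridge predates all three intervals for the
*T. bruneri* split — and the computed decisions match the recorded ones on
all 14 rows.

The same machinery runs end-to-end on synthetic data with known truth:

```python
cfg  = bg.SimulationConfig(n_tips=12, implant_vicariance=(1,), seed=5)
tree = bg.simulate_dated_tree(cfg)
tips, truth = bg.simulate_range_evolution(tree, cfg)
recon = bg.diva_optimize(tree, tips)

from biogeodiva.routes import annotate_events
routes = annotate_events(recon, tree)
clade = tuple(truth.vicariant_clades[0])
print(routes[clade], recon.events[clade], recon.optimal_cost)
# BC|B^C ('vicariance',) 6
```

— the implanted split is recovered as a vicariant route (`BC|B^C`: an
ancestor in areas B+C splitting into a B daughter and a C daughter).

A command-line interface covers the same workflow
(`biogeodiva simulate | reconstruct | consensus | congruence | regress |
report`); every command logs its seed, rule choices and a SHA-256 hash of
each output file.

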
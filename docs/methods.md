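# Methods

## The notification network

A notification log is an ordered list of records `(date, detector,
transgressor, type, hazard_text)`.  The network at a query date *t* is
directed and weighted: the edge detector → transgressor carries

    w(d→g; t) = Σ_{notifications (d,g) with date t_i ≤ t} 2^(−(t − t_i)/τ)

with half-life τ = 180 days.  The half-life is the model's defining
constant: a report's influence is 1 on the day it is logged, exactly 1/2
after 180 days, 1/4 after 360, and so on.  The exponential form is this
package's modelling choice; it is the unique memoryless decay consistent
with a stated half-life, and it makes edge weights additive over
notifications and monotonically "forgetful" as the query date advances.
Ages are measured in whole days; records dated on the query date contribute
weight 1 (closed inclusion boundary); records dated after it are excluded,
not extrapolated.  Parallel notifications between a pair are aggregated
into one edge — every downstream algorithm consumes aggregate weights.
Decayed weights never reach zero, so `min_weight` (default 0, i.e. no
pruning) exists to drop negligible edges for display; pruned edges leave
their endpoint countries in the node set.  Self-reports (detector =
transgressor) are permitted and flagged, not rejected.

## Indices

Both index families are L1-normalized so that, at any date, each vector is
a probability distribution over countries.  This is the interface contract
everything else (colours, trajectories, exports) relies on.

**PageRank.**  TI = weighted PageRank of the detector → transgressor
orientation; DI = the same computation on the reversed graph.  Power
iteration with damping 0.85 (the standard value; exposed as a parameter),
tolerance 1e−10 on the L1 residual, cap 1000 iterations, error with the
residual on non-convergence.  Dangling nodes — pure transgressors have no
out-edges in the TI orientation — teleport uniformly, the standard
completion that keeps the index a proper distribution.  The TI and DI are
computed independently of each other.

**HITS.**  On the detector → transgressor orientation, DI = hub scores and
TI = authority scores, by weighted mutual-reinforcement iteration
(`a ← Wᵀh`, `h ← Wa`).  Internal iterations normalize in L2 for numerical
stability; the converged fixed point is L1-normalized to meet the
sum-to-one contract.  A snapshot with no edges is an error for HITS (there
is no reinforcement fixed point), whereas PageRank degenerates gracefully
to the uniform distribution.

Countries with zero score are retained in the vector rather than dropped,
keeping export schemas stable across dates; ranking ties break
lexicographically by country code so reports are deterministic.  For
display, scores are multiplied by `report_scale` (default 1000).

Both engines are validated against independent oracles that take different
computational routes: PageRank against a dense linear-system solve of the
stationarity equations, HITS against both a symmetric eigendecomposition
of `WᵀW` and a long-run explicit-matrix iteration, plus networkx's
implementations as a third route.  Agreement is within 1e−8 on 100 random
weighted digraphs of ≤ 8 nodes.

## Categorization and filters

Hazard texts are matched case-insensitively as raw substrings (no
stemming — the keyword table lists literal contaminant components) against
a fixed table: metals (arsenic, lead, mercury, cadmium), mycotoxins
(aflatoxin, fumonisin, ochratoxin), bacteria (salmonella, bacillus cereus,
listeria monocytogenes), chemicals (benzoic acid, colour sudan 1,
methomyl, nitrofuran, sulphites) and other (chloramphenicol, dioxins,
methamidophos).  No match → `uncategorized`; such records still count in
unfiltered ("all") analyses.  When keywords from several categories match,
the first category in table row order wins, with a warning and all matches
kept in a diagnostics field — the tie-break is a convention, chosen for
determinism.  Matching is applied to the hazard text field only.  Filters
compose a category restriction (including `microorganism` = mycotoxin ∪
bacteria) with a notification-type restriction (all vs. border rejections);
an empty result is a valid empty log.

## Structure analytics

Community detection and coreness run on the undirected projection with
opposite-direction weights summed (direction encodes roles, not
separation; the projection asks only who interacts with whom).  Modularity
is Newman's weighted Q.  `find_communities` is greedy multilevel (Louvain)
optimization, run with 8 seeded restarts keeping the best Q — the
heuristic is stochastic and restarts are cheap insurance on small graphs;
with the default seed it attains the exhaustive-search optimum on every
benchmark tested (two disjoint triangles, Q = 0.5; a planted two-block
graph; random graphs of ≤ 7 nodes).  The returned Q is recomputed from
the assignment, so it is always consistent with `modularity()`.  Coreness
ignores weights and self-loops and matches a brute-force peeling oracle on
random graphs of ≤ 12 nodes.  Whether to threshold weak edges before
k-core is left to the caller via `min_weight`; the default applies none.

## Colour coding

Node colours encode the two roles: red intensity = min(1, TI · s), green
intensity = min(1, DI · s), opacity = max(red, green).  Strong
transgressors render deep red, strong detectors deep green, dual-role
countries brownish, and countries negligible in both roles transparent.
The strength scale *s* defaults to 1 / (95th percentile of the pooled TI
and DI values at the query date), so colour saturates for the top actors
regardless of network size.  The transfer function is this package's
choice, documented rather than claimed canonical.

## Synthetic scenarios

The generator emulates the coarse statistics of the EU surveillance
stream so every stage is testable without the non-distributable extract:

* **Countries and roles** — per-country `detect_rate` and
  `transgress_rate`; detectors are drawn (∝ detect_rate) from a
  configurable member-state pool, mirroring a system where only EU members
  file reports while any country can be reported against.  Self-pairs are
  resampled unless explicitly allowed.
* **Dates** — uniform over the scenario window (the default window is
  May 2003 – Aug 2008, the span of the reference stream).  Seasonality is
  deliberately not modelled.
* **Categories** — drawn from a mixture defaulting to the categorized
  stream's proportions (mycotoxin 50.45%, bacteria 20.26%, metal 10.95%,
  chemical 15.54%, other 2.80%); the hazard text is a keyword sampled from
  the drawn category's row, so generated logs are always categorizable.
* **Types** — border rejections with probability 0.25 (a deliberately
  prominent share for a class described as major; the true share is not
  published), the rest split evenly between alert and information.
* **Interventions** — dated `rate_change_events` re-set a country's
  transgress rate, emulating remediation: zeroing a rate produces a TI
  trajectory that decays from one half-life after the cut.

Everything is driven by one `numpy` generator seeded from the scenario
seed, so identical configs give byte-identical logs.

What passing tests on generated data do **not** show: real streams have
seasonal and epidemic bursts, correlated hazards per incident, free-text
hazard descriptions far messier than single keywords, and reporting-policy
changes over time.  Results on synthetic logs validate the machinery
(decay arithmetic, engines, filters, exports), not substantive conclusions
about any real country's food-safety behaviour.

## Problem sizes and numerical choices

Index engines build dense matrices ordered by sorted country code —
country networks have at most a few hundred nodes, where dense linear
algebra is both fastest and simplest.  Convergence tolerances are L1
residuals (1e−10 by default) with hard iteration caps and explicit errors
on non-convergence.  Validation suites use 100 random digraphs of ≤ 8
nodes for engine oracles, exhaustive partition search up to 10 nodes
(115,975 partitions) for modularity optima, 200 replicates of a 10-country
scenario with 400 notifications each for planted-role recovery, and
15,000-record logs for mixture fidelity — sizes chosen so the whole suite
runs in well under a minute while keeping multinomial noise far below the
tolerances checked.

## Known limitations

* The decay's functional form beyond its half-life, the PageRank damping
  factor and the colour transfer function are this package's documented
  choices; original tools in this field may differ in these unstated
  details.
* Input is delimited text with ISO-8601 dates only; spreadsheet export is
  provided (`.xlsx`), spreadsheet *input* is not.
* Snapshots are rebuilt per query date; there is no incremental streaming
  update path.
* Overlapping communities and layered-structure visualisations beyond
  coreness values are out of scope.
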
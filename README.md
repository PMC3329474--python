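# rasffnet

Network analysis of food-safety notification streams.

EU food- and feed-safety surveillance (the RASFF system) logs thousands of
notifications per year, each recording that a *detector* country reported a
faulty product originating from a *transgressor* country, on a date, with a
notification type (alert, information, border rejection) and a free-text
hazard description.  Frequency counts on such a stream hide who reports
whom: a country's impact depends on the relationships, volumes and recency
of its reports, not just their number.  `rasffnet` treats the stream as a
time-decayed directed network and computes normalized per-country impact
indices on it, for regulatory analysts, food-safety researchers and anyone
monitoring remediation measures over time.

## Model

From a notification log, the network at a query date *t* is a directed
weighted graph: nodes are countries, and the edge detector → transgressor
has weight

&nbsp;&nbsp;&nbsp;&nbsp;w(d→g; t) = Σ over notifications (d, g, tᵢ ≤ t) of 2^−(t−tᵢ)/τ,&nbsp;&nbsp; τ = 180 days,

so each report contributes 1 on the day it is logged and half that 180 days
later — recent activity dominates, old activity fades but never vanishes.

On each snapshot two index families are computed:

* **Transgressor Index (TI)** and **Detector Index (DI)** by **PageRank**
  (damping 0.85, uniform teleportation for dangling nodes): TI is the
  weighted PageRank of the detector → transgressor orientation, DI of the
  reversed orientation.  The two roles are computed independently.
* TI and DI by **HITS**: authorities and hubs of the detector →
  transgressor orientation.  Here the roles are mutually reinforcing — a
  DI is high for a country reporting against high-TI countries and vice
  versa.

Every index vector is L1-normalized: scores sum to 1 across countries at
any date, so a score is a share of total activity and trend lines of
different countries are directly comparable.  Reports conventionally
display scores × 1000.

Notifications are auto-assigned a contaminant category (metal, mycotoxin,
bacteria, chemical, other) by case-insensitive keyword matching on the
hazard text; filters restrict analyses by category (including the combined
*microorganism* = mycotoxin + bacteria class) and by notification type
(all vs. border rejections only).  Structural analytics — modularity-based
community detection and k-core decomposition — run on the undirected
projection of a snapshot.  A synthetic-log generator with planted roles,
category mixtures and dated rate-change events makes every stage testable
without the original surveillance extract.

## Worked example

```sh
rasffnet simulate --n 2000 --seed 1 --out demo_log.csv
rasffnet snapshot --input demo_log.csv --date 2008-01-01 \
    --filter-category mycotoxin --method hits --out demo_snap
head -4 demo_snap/indices.csv
```

prints

```
wrote 2000 notifications to demo_log.csv
country,method,role,date,filter,score,score_x1000
ARG,hits,TI,2008-01-01,mycotoxin,0.06530295179473283,65.30295179473283
BRA,hits,TI,2008-01-01,mycotoxin,0.05535818409783238,55.35818409783238
CHN,hits,TI,2008-01-01,mycotoxin,0.16581818911477025,165.81818911477026
```

The snapshot aggregates all mycotoxin-related notifications logged up to
1 January 2008, decayed by age.  In this simulated scenario the top HITS
transgressor indices (×1000) are IRN 168.7, CHN 165.8 and TUR 161.0 — the
countries the scenario endows with the highest transgress rates — while
the top detector indices go to the high-volume reporters DEU 304.0,
GBR 145.8 and ESP 120.6.  Because each vector sums to 1, IRN's 168.7 means
roughly 17% of all mycotoxin transgressor impact at that date.  The output
directory also contains the GraphML graph with red/green node colours
(deep red = strong transgressor, deep green = strong detector, brownish =
both, transparent = marginal), the edge list, and a JSON run manifest.

Trend lines and structure:

```sh
rasffnet trajectory --input demo_log.csv --dates 2005-01-01:2008-08-01 \
    --select IRN,CHN --scale 1000 --out demo_traj
rasffnet communities --input demo_log.csv --date 2008-01-01 --out demo_comm
```

The same operations are available as library functions (`read_log`,
`filter_log`, `build_snapshot`, `pagerank_indices`, `hits_indices`,
`index_trajectory`, `find_communities`, `k_core`, `generate_log`, ...);
see `docs/methods.md` for the modelling details and parameter defaults.

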
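# screenminer

Share and visually analyse high-content microscopy screen data without a
GUI, a database server, or specialist tooling on the consumer's side.

High-throughput/high-content screening (HT/HCS) produces feature tables
of millions of segmented objects — cells with hundreds of morphology and
intensity measurements, organised under the genes or conditions that were
perturbed. After a screen is published, just *looking* at that data
usually requires image-analysis expertise. `screenminer` packages a
screen as a small, portable **property graph** — objects of interest as
nodes carrying property tuples and binary labels, connected by
membership/derivation edges — built from a single typed CSV file, and
puts a complete query-and-analytics toolkit on top of it:

* **multi-level querying** — the same features viewed per *grouping*
  object (gene, strain, condition) or per *descriptive* object (cell),
  with per-gene aggregation (mean/median/count/min/max), conjunctive
  filters at either level (labels, numeric ranges), log10 axis
  transforms and rectangular area selection (gating);
* **gene-to-cell drill-down** — expand any gene-level selection into the
  member cells that compose it;
* **analytics** — (multi)histograms, Gaussian kernel density estimates
  with Silverman's bandwidth
  `h = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)`, ordinary least-squares
  regression lines with `r² = 1 − SS_res/SS_tot`, and plot comparison;
* **reproducibility surface** — CSV raw-data export, SVG plot export,
  and self-contained share tokens: a URL-safe string that replays a
  complete query (including every filter) byte-for-byte;
* **a read-only JSON HTTP API** so other languages and pipelines can
  query a served instance;
* **a deterministic synthetic-screen generator** (genes × cells ×
  features with planted effect sizes and hit labels) so the whole stack
  is testable with known ground truth.

## Input format

A screen CSV has three header rows, then one descriptive-object instance
per line:

1. column headers — the property names;
2. object names — which object each column belongs to (`Gene`, `Cell`,
   `Image`, …);
3. property types — `ID` (object identity, several allowed), `NUMBER`
   (a queryable feature), `TEXT` (metadata), `URL` (link-out, e.g. to a
   raw image in an image store).

An optional label CSV annotates the grouping objects: the first *n*
columns are its IDs, every other column is binary (1 = the object
possesses that label).

## Worked example

```sh
screenminer synth --genes 4 --cells 5 --features 2 --hits 1 --seed 3 --out fx
screenminer build --data fx/screen_data.csv --labels fx/screen_labels.csv \
    --grouping Gene --descriptive Cell --out instance.jsonl
# -> labels: 1 grouping objects annotated (4 rows applied)
# -> instance written to instance.jsonl: 4 Gene, 20 Cell, 40 edges
```

```python
from screenminer import (PropertyGraph, QueryState, FilterClause,
                         run_query, drill_down, fit_regression,
                         encode_share)

graph = PropertyGraph.load("instance.jsonl")
state = QueryState(
    level="grouping", x_feature="feat_01", y_feature="feat_02",
    aggregation="mean",
    filters=(FilterClause("Gene", "label-presence", "hit"),))
points = run_query(graph, state)
for rec in points.records:
    print(rec.entity_ids[0][1], round(rec.x, 3), round(rec.y, 3))
# g0004 11.26 15.078          <- the one hit gene's per-cell means
print(str(encode_share(state))[:40])
# v1.eNptjUEOgkAMRe_SNSbqkgt4CGNIhc84sRRSi  <- shareable replay token
cells = drill_down(graph, ["g0004"], "feat_01", "feat_02")
print(len(cells))             # 5 member cells of the selection
fit = fit_regression(cells)
print(f"slope {fit.slope:.3f}  r^2 {fit.r_squared:.3f}")
# slope -0.036  r^2 0.001     <- the two features are independent
```

`screenminer serve --instance instance.jsonl --port 8080` exposes the
same operations over HTTP (`POST /query`, `/histogram`, `/kde`,
`/regression`, `/compare`, `GET /catalog/{kind}`, `GET /share/{token}`,
`GET /health`), returning plot-ready canonical JSON.

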
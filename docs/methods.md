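# Methods

## Data model

A screen is stored as a property graph. Node kinds play one of three
roles: exactly one **grouping** kind (the perturbation unit — gene,
strain, condition), at most one **descriptive** kind (the measured
object, typically the cell; when a screen has a single data layer, the
grouping kind is flagged self-descriptive and carries the measurements
itself), and any number of **metadata** kinds (images, wells,
experiments). Nodes hold a property tuple — numeric features, text
metadata, URL link-outs — plus a set of binary labels; external identity
is always the pair (kind, ordered ID property values), with the integer
node id a private surrogate. Edges are directed from the detailed object
towards its context (cell → gene, cell → image); a descriptive node's
owning grouping object is the unique grouping node reachable along
outgoing edges, and the import fails a query with `GraphIntegrityError`
if that node is not unique.

The store is a plain in-memory adjacency index with a JSON-lines
serialization (kinds, per-kind catalogs, nodes, edges, each sorted), so
equal graphs serialize byte-identically and the format diffs cleanly
under version control. There is deliberately no database backend and no
transactional contract: an instance is built once by the importer and
then served read-only.

### Import conventions

* CSV dialect: RFC 4180, UTF-8, decimal point, no thousands separators.
* Property-type tokens (`TEXT`/`NUMBER`/`ID`/`URL`) match
  case-insensitively; anything else is a `FormatError` naming the token
  and column.
* Rows repeating an existing (kind, ID-tuple) **merge** into the node;
  a conflicting value for an already-set property is an
  `ImportConflictError`. Merging is what makes the format work — many
  cell rows reference one gene. Repeated edges collapse to one.
* Empty `NUMBER` cells are *missing*: excluded from catalogs of values,
  aggregation, and query output (with a reported dropped count) — never
  coerced to zero.
* Every object named in the schema needs at least one `ID` column,
  otherwise its rows could not be merged into nodes.
* The format itself does not say which object is grouping and which is
  descriptive, so the operator states it (CLI flags). Left unset, the
  owner of the first `ID` column is taken as grouping and the owner of
  the most `NUMBER` columns as descriptive — a heuristic that matches
  how such tables are conventionally laid out.
* The label file is assumed to carry one header row (ID column names,
  then label names); rows whose IDs match no grouping node are collected
  as warnings rather than failing the import, since screens routinely
  annotate genes absent from an imported subset.

## Query semantics

A query is a declarative, JSON-serializable state: level, axis features,
aggregation method, a conjunction of filters, axis transforms, and an
optional selection rectangle. Evaluation order is fixed and documented
because the result depends on it:

1. descriptive-level filters on the raw objects (a grouping-targeted
   clause at descriptive level is evaluated on the owning group);
2. aggregation to grouping objects (grouping level only), each axis over
   its own non-missing member values; a group with no usable value on a
   requested axis is dropped and counted;
3. grouping-level filters;
4. axis transforms (`linear` or `log10`; log10 of a non-positive value
   raises `TransformError` listing the offending entities rather than
   silently dropping them);
5. the area selection, interpreted as a **closed** rectangle in
   displayed (post-transform) coordinates, since that is the space the
   user gated in.

Cell-level filters are applied *before* aggregation: filtering is meant
to restrict which cells contribute to a gene's summary, not to censor
already-summarised genes. Filters are conjunctive and therefore
order-independent; records are sorted by entity IDs so identical queries
always produce byte-identical output. The aggregation method is an
explicit query field (default mean) rather than a hidden convention;
median of an even count is the average of the middle two.

## Analytics conventions

* **Histogram**: equal-width bins over `[min, max]`; last bin
  right-closed, others right-open; default bin count is Sturges' rule
  `⌈log₂ n⌉ + 1`; constant data gets one unit-width bin centred on the
  value. Multihistograms share one binning over the pooled range.
* **KDE**: Gaussian kernel; automatic bandwidth is Silverman's
  rule-of-thumb `0.9·min(σ̂, IQR/1.34)·n^(−1/5)` with the IQR term
  dropped when it is zero (heavily tied data), the same fallback R's
  `bw.nrd0` uses; evaluation grid is 256 points over `[min − 3h,
  max + 3h]`, or any caller-supplied grid. Both kernel and bandwidth are
  overridable.
* **Regression**: ordinary least squares on the coordinates as
  displayed; `r² = 1 − SS_res/SS_tot`, declared degenerate (and set
  to 0) when `SS_tot = 0`; constant x is an error (vertical line).
* **Plot comparison** returns data, not pictures: shared (union) axis
  ranges, per-set summaries and their differences. No hypothesis test
  is attached — the tool compares, it does not decide.

## Sharing and the service

A share token is the canonical JSON of a query state (sorted keys, no
whitespace, shortest round-trip decimals), deflate-compressed,
base64url-encoded without padding, and prefixed `v1.`. Tokens are
self-contained — no server-side state — so a link keeps working wherever
the instance file goes; tampered or future-version tokens fail loudly.
The HTTP service is a thin WSGI layer over the library: every endpoint
re-enters the same `run_query`/analytics code paths, and nothing in the
API can mutate a loaded instance. The route layout (`/query`,
`/histogram`, `/kde`, `/regression`, `/compare`, `/share/{token}`,
`/catalog/{kind}`, `/health`) is this package's own design.

## Synthetic screens and what they do (not) show

The generator emulates the structure of a perturbation screen: genes ×
cells × numeric features plus a binary hit-label file. Cell values are
independent Gaussians, `Normal(μ_j + s·σ_j, σ_j)` per feature *j*, with
the planted shift *s* (in within-gene SD units) applied to hit genes;
default study conditions are 50 genes × 100 cells × 10 features, 5 hit
genes, effect size 2.0 on the first feature. Default feature scales
(`μ_j = 10 + 5j`, `σ_j = 1 + 0.25j`) put features on distinct positive
scales like real morphology measurements. An optional paired channel
replaces the last feature with `a·feat_01 + Normal(0, σ_noise)` to give
regression a known slope, and a missing-value rate exercises the
missing-data paths. Image IDs group 25 cells per image and URLs are
templated placeholders on a reserved `.invalid` host — never fetched.

The generator is deliberately simple: features are uncorrelated, there
are no plate/batch effects, no outliers, no segmentation artifacts, and
cell counts are balanced unless specified per gene. Tests passing on
this data therefore demonstrate the *bookkeeping* of import, querying,
aggregation, sharing and transport — not robustness to the pathologies
of real screens.

Acceptance-style checks run on the 50×100×10 conditions above
(5,000 cells), 100 random queries against an independent pandas
re-implementation, KDE at n = 10,000, and 100 simulated regressions of
n = 200 cells each — sizes chosen so the whole suite re-derives every
claim from scratch in well under a minute on one core.

## Known limitations

* One grouping kind and one descriptive kind per graph; deeper
  hierarchies (e.g. gene → well → cell as *queryable* levels) are
  representable as metadata but not queryable levels.
* Filters are conjunctive only; disjunction is deferred.
* Axis transforms are limited to linear/log10.
* The service carries no authentication; it is intended for the public
  data-sharing use case behind whatever deployment-level access control
  the operator chooses.
* Single-writer store: no concurrent mutation guarantees.
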
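# Methods

## Effect propagation and the TI index

The package treats a food web as a binary, undirected graph. The one-step
effect matrix `M` is defined by `M[i, j] = 1/D_j` for every edge `{i, j}`,
where `D_j` is the degree of `j`: a node splits the influence it receives
equally among its neighbours, making every non-isolated column of `M` sum to
one. Multi-step effects are matrix powers — sums over *walks*, not simple
paths, so influence may revisit nodes; this is the standard choice in the
topological-importance literature and is what the brute-force enumeration
oracle in the test-suite verifies against. `TI^n` averages the 1..n step
effects with the factor `1/n`; a plain-sum aggregation is available for
sensitivity checks and differs only by the constant `n`. The horizon
defaults to `n = 3`: longer chains of indirect effects decay quickly, and
three steps are conventionally taken to capture the ecologically meaningful
range.

Normalisation divides all entries by the grand off-diagonal total so the
TI matrix sums to one over ordered pairs. This is one scalar rescaling and
therefore cannot change the rank order of entries: the asymmetry graph's
node set, link set and orientation are invariant to it, and only reported
link weights depend on the convention. The diagonal is zeroed — a node's
self-asymmetry is identically zero and self-effects are never used.

## The asymmetry graph

For each unordered pair, `A_ij = |TI^n(i,j) − TI^n(j,i)|`. All `N(N−1)/2`
pairs compete for retention — not only food-web edges, because indirect
effects can be strongly asymmetric. The retained count (link budget) is
`max(1, floor(t·N(N−1)/2))` with `t = 0.01` by default. The floor is used
because it reproduces the observed budget on larger webs (22 links at
N = 67), while the minimum of one keeps small webs informative (at N = 8
the raw budget is 0.28 pairs and is promoted to a single link). Each
retained pair is oriented from the stronger affecter to the weaker and
weighted by `A`.

Numerical choices: exact-zero asymmetries are never admitted even when the
budget is unfilled (a zero-weight causal link is meaningless — this is what
makes vertex-transitive graphs such as cycles and complete graphs yield
empty asymmetry graphs); ties at the cutoff rank are broken by the
deterministic order (asymmetry descending, source label, target label),
which makes link sets nested across thresholds and runs reproducible.
The DAG check and the weak-component count operate on incident nodes only;
an empty graph has zero components and is vacuously acyclic.

## Trophic levels and link polarity

Prey-averaged trophic level (the Ecopath convention): basal species have
level 1, every consumer is one plus the mean level of its prey. The
definition is solved as an exact linear system, so feeding loops are
admissible whenever each consumer community ultimately draws on basal
production; a closed consumer cycle with no such anchor makes the system
singular and is reported with the offending strongly connected component.
If an attribute file supplies precomputed levels, those take precedence
(`method="provided"`), covering collections whose source models already
report TL. An asymmetry link from lower to higher level is bottom-up, the
reverse top-down; links between levels closer than 1e-9 are "lateral" and
counted in neither — silently binning ties either way would bias the
TDag/BUag ratio. That ratio is reported missing (not 0 or infinity) when
BUag = 0, and drops out of correlations by pairwise deletion.

## Indicators

Conventions where the bare definitions leave latitude:

* Connectance `Cfw = Lfw/(N(N−1)/2)` — the undirected pair universe, the
  same universe the link budget draws from.
* `avDISTfw` averages shortest-path lengths over connected unordered pairs
  of the undirected graph; unreachable pairs are excluded and logged
  (dropping infinities is the only finite convention).
* `Tfw` is global transitivity, 3·triangles / connected triples — not mean
  local clustering.
* The carnivore/omnivore ratio counts `TL > 2 + 1e-9`, so exact herbivores
  (TL = 2.0) are excluded.
* `Sh` uses biomass proportions and the natural log (Ecopath models supply
  biomass, not abundance); `TB` is the plain biomass sum.
* `EE` averages ecotrophic efficiencies inside [0, 1]; values outside are
  "unrealistic" under Ecopath mass balance and are omitted with a log entry
  naming node and value. The range is configurable.

The per-web pipeline records failures (no trophic information, edgeless
webs) as missing cells and continues the batch, so one malformed model
never aborts a collection run.

## Correlation screen

Kendall's tau-b (tie-corrected — count-valued indicators tie heavily in
collections of a few dozen webs) with two-sided p-values, pairwise-complete
deletion per variable pair, and Benjamini–Hochberg step-up adjustment
applied jointly across every pair with a computable p-value (constant or
too-sparse columns are excluded from the family and logged). Significance
is declared at adjusted q < 0.05; the heatmap export stars q at
0.05/0.01/0.001. The suite verifies FDR control empirically: on 1000
global-null indicator tables (21 independent noise variables, 34 rows) the
fraction of tables with any discovery stays within the binomial band
around 0.05.

## Synthetic webs

The generator produces niche-model topologies: species at uniform niche
positions consume everything inside a contiguous feeding range of
beta-distributed width calibrated to a target directed connectance
`L/N²`, with range centres below the consumer's own position. One
deliberate departure from the plain niche model: a fixed **basal fraction**
(default 0.2) of species — the lowest niche positions — get zero-width
ranges. The plain model's basal fraction shrinks with web size and
connectance, diverging from empirical webs, whose producer share is roughly
constant; fixing it keeps resource-base breadth proportional to richness,
which is what couples total biomass to web size in realistic collections.
Consumer range widths are rescaled by `1/(1−f²)` so realized connectance
still matches the target on average (the residual ~0.01 upward bias comes
from conditioning on connectedness, since sparse disconnected draws are
rejected). Trophically duplicate species (identical prey and predator
sets — common among interval-fed basal species) are resolved by redrawing
the offenders in place; whole-web draws are rejected and redone if
disconnected, basal-free, or trophically unsolvable, up to a bounded number
of attempts.

Attributes emulate Ecopath outputs: biomass lognormal with median
`B₀ · d^(TL−1)` (defaults `B₀ = 100`, decay `d = 0.1` per level — a steeply
bottom-heavy biomass pyramid — shape σ = 1) and EE uniform on [0, 1].
Collections draw per-web sizes uniform on {51..120} (all above the 50-node
selection cut used for real collections) and connectance uniform on
[0.05, 0.15], the range typical of large Ecopath models. All randomness
descends from one integer seed through numpy's Generator, so webs and
attributes are bit-reproducible across runs and platforms.

What passing tests on these webs show — and what they do not: the synthetic
collections exercise every pipeline stage and reproduce directional,
scale-free behaviour (budget scaling, FDR control, the positive TB–BUag
association driven by resource-base breadth). They are not mass-balanced
Ecopath solutions: biomass and EE are generative stand-ins, detritus loops,
multi-stanza groups and sampling idiosyncrasies of real models are absent,
so quantitative indicator values on real collections will differ even where
the qualitative structure matches.

## Problem sizes and determinism

Default test and example runs use collections of 34 webs of 51–120 species
and oracle graphs of at most 8 nodes — sizes at which exhaustive walk
enumeration is feasible and a full collection pipeline completes in
seconds. The TI computation is dense linear algebra (`O(N³)` per web for
the matrix powers) and comfortably handles the few-hundred-node webs found
in public repositories. Every stochastic component takes an explicit seed;
nothing reads clocks or global random state.

## Known limitations

* The weighted/directed effect variant (propagating diet proportions
  instead of binary topology) is out of scope; diet matrices are binarised
  on read. Flow-weighted trophic levels are likewise a documented extension
  point, not implemented.
* The normalisation convention of TI matrices affects reported weights;
  only scale-free quantities should be compared across implementations.
* Year-deduplication of model collections is delegated to a user-supplied
  exclusion list; the package does not read model metadata.
* No network access: comparisons against repository models require the user
  to export diet matrices themselves, and exact node/link counts then
  depend on the binarisation choices documented in the README.
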
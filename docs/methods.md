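# Methods

## Scope and data model

The package operates on genes × samples expression matrices
(`ExpressionMatrix`, which records whether values are raw intensities,
normalized ratios, or log2) accompanied by a per-sample design table
(`StudyDesign`: system, compound, dose, time, replicate, control flag).
Three study shapes are supported throughout: a dose-series design (several
dose groups × time points × replicates), a two-group control/treated
design, and large heterogeneous compendia used only for network inference.

## Preprocessing

Order: floor → per-chip → sample QC → per-gene → presence filter → log2.

* **Floor at 5.0 intensity units.** Scanner values below 5 are noise-level;
  flooring stabilizes the downstream ratios. Applied before normalization
  (flooring after division would make the floor sample-dependent).
* **Per-chip normalization** divides each array by its 50th percentile
  (linear-interpolation median, the common convention; the percentile
  definition is fixed in one place so an alternative could be swapped in).
* **Sample QC** computes, on log2 per-chip-normalized values, each array's
  mean Pearson correlation with all other arrays and excludes arrays with
  mean r < 0.80 in a single pass. Two deliberate choices here. First,
  single-pass (not iterative) exclusion: the result is deterministic and
  independent of removal order. Second, QC runs *before* per-gene
  normalization: between-array correlation is carried almost entirely by
  the shared probe-brightness profile (bright probes are bright on every
  sound array, r ≈ 0.95), which is precisely the structure per-gene
  normalization removes — after it, even perfect replicate arrays
  decorrelate toward 0 and a fixed 0.8 rule would reject everything.
* **Per-gene normalization** divides each probe by its across-sample
  median, so downstream values are fold-relative to each gene's typical
  level.
* **Presence filter** keeps probes flagged present on at least 50% of
  arrays (inclusive ≥, so exactly half qualifies); P/A and 1/0 flag
  dialects are both accepted and anything else is a parse error.
* Missing values are not supported: an NA cell is a parse error, since the
  flag filter is the designed mechanism for unreliable measurements.

## Differential expression

The dose-series filter runs a classical fixed-effects one-way ANOVA across
dose groups per gene at one time point; the study-level gene list is the
union over time points. The two-group filter is an equal-variance Student
t-test (Welch available behind a flag; the equal-variance form is the
default because group sizes are tiny and equal by design). Both filters
require raw p < α (strict, α = 0.05) *and* a max-pairwise fold change
≥ 1.5 (inclusive). Fold change is computed on linear-scale group means —
log2 data are exponentiated first — as max(means)/min(means) over dose
groups, so it is ≥ 1 by construction. Degenerate all-constant genes get
p = 1 (no evidence) rather than an error, so they flow through and fail.

No multiple-testing correction affects the pass flag, matching the raw
p < 0.05 convention of the workflow this reproduces; Benjamini–Hochberg
q-values are emitted as an informational column. Direction is classified
from the top-dose (or treated) mean against the control mean and is
`none` exactly for non-passing genes.

## Clustering

Condition profiles are built by dividing each sample by the mean of its
stratum's controls (stratum = system × time point) and averaging
replicates within each (system, compound, dose, time) condition. Both axes
are clustered by UPGMA on centred Pearson dissimilarity d = 1 − r
(uncentred Pearson is a noted alternative; centred is used because the
control-ratio transform already anchors the scale). The agglomeration is
implemented directly with a deterministic tie-break — equal-dissimilarity
merges resolve by the lexicographically smallest representative-label
pair — so trees are identical across platforms and input orders. Trees are
exported as Newick with branch lengths equal to the height difference
between parent and child merges.

## CLR network inference

Mutual information uses B-spline soft binning: values are linearly mapped
onto the spline domain over [min, max], each sample receives fractional
membership across 10 bins via order-3 B-spline basis functions on a
uniform knot vector with order-fold repeated boundary knots (partition of
unity holds row-wise to 1e-12), and the joint bin distribution is the
sample-average outer product of the two membership vectors. MI is the
plug-in value in bits (log base 2; natural log available). Order 1
degenerates to hard equal-width binning, which is the oracle used in
tests. A constant profile admits no binning and contributes MI = 0.

CLR scoring standardizes each pair's MI within both endpoints' background
MI distributions (all MIs to *other* genes; diagonal excluded; population
denominator). Negative z-scores are clamped to zero before squaring —
without clamping, two genes whose MIs to everything are merely low would
score high together — and the composite is √(z_A² + z_B²). The 2.0 cutoff
applies to the composite (not to each endpoint separately) and is
inclusive. Genes with zero background spread contribute z = 0. Both the
clamp and all estimator parameters are recorded in the network metadata.

Practical note established during development: the composite-z threshold
is only informative on a *module-dense* gene panel. Within such a panel
(e.g. the common differentially expressed genes, which is also how the
pipeline stages its network inference) every gene's background contains
genuinely dependent partners, so σ_bg reflects biology and z ≥ 2 demands
exceeding it. On a panel dominated by mutually independent genes the
backgrounds are estimator-noise flat, the empirical z is scale-free, and
~5–8% of *all* pairs exceed the cutoff no matter how many samples are
used. Thresholded networks should therefore be read on curated panels;
on broad panels the score *ranking* (AUPR, precision@k) is the meaningful
output.

## Conserved subnetworks

Edges are undirected unordered pairs (CLR is symmetric, so there is no
orientation to preserve). The conserved set is the exact edge
intersection; components are ordered by size then smallest member.
Per-component annotation joins each node to its DE direction in both
systems and flags components whose members agree everywhere. TF degree
tables flag hubs with strictly more than 15 connections; cross-system
bias flags a TF whose degree in one network is at least twice its degree
in the other (positive-vs-zero counts as biased, zero-vs-zero does not).

## Enrichment

A transparent stand-in for proprietary knowledge-base tools: upper-tail
hypergeometric P[X ≥ k] of a gene list against user-supplied GMT sets,
restricted to an explicit universe, with BH q-values alongside and
significance at raw p < 0.05. It makes no attempt to reproduce any
proprietary category system, and overlapping categories receive no
independence correction (none is defined for them).

## Synthetic data

The generator plants two TF-module truth networks that share a conserved
core (shared modules are identical in endpoints and signs; slope
magnitudes are drawn per system, so the core shares topology and
direction but not exact kinetics; the two systems never replicate a
non-shared regulator→target pair). Expression follows a linear-Gaussian
model on the log2 scale: each TF has a latent per-sample activity =
dose-response term (linear in log dose by default; Hill optional) plus
Gaussian variation — drawn per array in compendia (sd `effect_sd` = 1.0,
the compound-to-compound heterogeneity) and per replicate in designed
studies (sd 0.3, animal/culture-level variation); targets add signed
slope × activity; every gene adds its baseline and N(0, 0.3²) measurement
noise; values are exponentiated to the intensity scale so the full
normalization chain (including flooring, presence flags derived from
intensity, and QC) is exercised.

Default scales, chosen once for realism: baselines N(9, 2.5²) log2 (real
array intensity spreads; this shared profile is also what makes sound
arrays correlate at ~0.95 so QC behaves as on real chips); hub TFs swing
6 log2 units at top dose (the many-ten-fold inductions of xenobiotic
master responders); target slopes 0.20–0.26, i.e. ~2.3–3-fold target
responses and a regulator–target compendium correlation near 0.55–0.6;
compendia of 240 arrays (network-compendium scale). Linear-Gaussian
regulation was chosen over ODE simulation because it produces exactly the
dependence structure MI-based inference assumes, with analytically
controllable signal-to-noise. All randomness descends from one seed
through per-(stream, system, gene) counter-based substreams, so enlarging
the gene panel does not perturb the values of existing unconnected genes.

What the simulator does *not* emulate: probe-level noise physics (dye
bias, spatial artifacts), fan-in (each target has one regulator),
feedback, time dynamics, and count-based RNA-seq noise. Passing tests
therefore demonstrate that the chain recovers planted linear-Gaussian
structure under realistic noise — not that it would perform identically
on real arrays.

## Known limitations

* **Transitive co-target edges.** If two targets are conditionally
  independent given their shared regulator, their correlation is forced to
  r_sib = r₁·r₂·(1 + σ²_noise/σ²_activity) — essentially the square of the
  direct-edge correlation. Whenever direct edges clear the composite
  z ≥ 2.0 cutoff robustly, a substantial fraction of co-target pairs in
  the *same* module clears it too, in both systems, and these genuinely
  conserved indirect dependencies populate the conserved set alongside
  the direct edges (in the worked example, roughly half the conserved
  edges). CLR has no data-processing-inequality pruning (that is ARACNE's
  contribution), so scored against a regulator→target gold standard the
  conserved set shows high recall (~0.9) but modest precision (~0.45);
  a calibration scan over slope and compendium-size settings shows the
  recall/precision frontier against such a gold standard capping near
  (0.85, 0.7). Conserved components should be read as conserved *modules*,
  not as literal regulator→target maps.
* Sample QC assumes corruption shows up as decorrelation from the cohort;
  a systematic batch shared by many arrays would pass.
* The DE filters use raw p-values by design; at panel scale this is the
  intended behavior of the reproduced workflow, not a recommendation for
  genome-wide screens.
* Networks are static: compendium-wide dependence, not condition-specific
  rewiring.
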
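# Methods

This note records the models, conventions, numerical choices and known
limitations of demesim, in the spirit of the methods documentation shipped
by mature simulation libraries.

## Demographic models and conventions

A model is a set of populations with, per population, a diploid effective
size, a per-generation exponential growth rate, and a row in a migration
matrix, together with a list of timed events. The conventions are fixed
once, package-wide:

* **Time** is in generations before present, increasing into the past;
  t = 0 is the (default) sampling time.
* **Sizes** are diploid effective sizes N; the pairwise coalescence rate
  within a deme is 1/(2N) per generation.
* **Migration** `m[i][j]` is the backwards-time rate at which a lineage in
  deme *i* traces to deme *j* — equivalently the forwards-time fraction of
  *i* replaced by migrants from *j* each generation. Diagonals are zero.
* **Growth** α is the backwards decay exponent: within an epoch starting at
  t₀ with size N₀, N(t) = N₀·exp(−α(t − t₀)). α > 0 means the population
  was smaller in the past (forwards growth).
* **Events at equal times** apply in listed order; this makes stacked
  split-plus-size-change constructions deterministic.
* **Coordinates** are 0-based half-open bp everywhere; VCF positions are
  converted to 1-based only at write time. 1 cM/Mb ≡ 10⁻⁸ crossovers per bp
  per generation.

### Canonical form and model QC

`canonicalize` decomposes a model into epochs tiling [0, ∞) over which all
rates are constant (sizes follow the epoch's exponential law), plus a
schedule of instantaneous lineage moves. Epoch boundaries appear only where
dynamics actually change, so syntactically different but semantically
identical event lists produce identical canonical forms; no-op events
(e.g. re-setting a rate to its current value, or a lineage move with
proportion 0) collapse. This is what makes `models_equal` a *semantic* test:
it compares canonical forms epoch-by-epoch at a relative tolerance
(default 10⁻⁶ — tighter than the precision of any published demographic
parameter, loose enough to absorb unit-conversion round-off), and reports
each discrepancy as (epoch interval, field path, value A, value B). The
population count and the lineage-move schedule must match structurally;
times and proportions of moves are compared at the same relative tolerance,
since independently re-derived floating-point times cannot be required to be
bit-equal while sizes are not. The intended workflow is
independent-reimplementation QC: a reviewer rebuilds a published model from
primary sources and the equality report either passes or names exactly what
disagrees — including the well-documented failure mode of migration left
switched on into a population during the most ancient, single-ancestor
epoch.

Model-definition files use a YAML mapping (id, description,
generation_time, populations, initial sizes/growth rates, migration matrix,
tagged event records, citations). Round trips are exact at the
canonical-form level, not the byte level; events listed out of time order
are accepted and sorted stably.

## The coalescent engine

The engine is a backwards-time structured coalescent with recombination
using Hudson-style ancestry tracking: each lineage carries a sorted list of
disjoint ancestral-material segments, each mapped to an output node and
annotated with the number of sample genomes descending from it.

* **Rates.** Within-deme pair coalescence at 1/(2Nᵢ(t)); per-lineage
  migration i→j at m[i][j]; per-lineage recombination at the genetic length
  (expected crossovers per generation) of the span between its first and
  last carried material.
* **Growth epochs.** Coalescence waiting times under an exponentially
  growing hazard are drawn by closed-form inversion of the integrated rate,
  capped at the epoch boundary — exact, with no time discretization. All
  other rates are constant within an epoch, so competing candidate times are
  drawn independently and the minimum wins; everything is redrawn after
  every event or boundary, which is correct for memoryless competing risks.
* **Recombination.** A breakpoint is drawn uniformly in *genetic*
  coordinates within the lineage's carried span and mapped back to a
  (floating-point) physical position, so piecewise-constant maps are handled
  exactly. Splits that would leave one side without material are no-ops.
* **Coalescence.** Two lineages merge by a linear sweep over their segment
  endpoints. Overlapping material produces edges to a single new node;
  non-overlapping material passes through unchanged (no node is created if
  nothing overlaps). Segments whose descendant count reaches the full
  sample size are fully coalesced and dropped. These rules give correct
  marginal trees and edge tables whose per-child intervals never overlap.
* **Lineage moves** relocate each lineage in the source deme independently
  with the event's proportion — the backwards-time encoding of population
  splits (proportion 1) and admixture pulses (< 1).
* **Mutations** are infinite-sites: Poisson on each edge with intensity
  μ × bp span × branch length, positions uniform on the edge interval and
  rounded to integer bp with collision redraw (collisions are negligible at
  the scales simulated here; the redraw guarantees unique site positions
  for VCF).
* **Termination guard.** Models in which lineages can never reach a common
  ancestor (disconnected demes) raise an error rather than hang: an
  immediate error if no event or boundary can ever occur, and a hard event
  ceiling (default 10⁷) otherwise.
* **Reproducibility.** One seeded generator per simulate call; the seed and
  the resolved configuration are embedded in a provenance sidecar, and
  re-executing from that record reproduces the tables byte-for-byte.
  Per-output sub-seeds for R×C fan-outs are derived by a counter-based
  SHA-256 hash of (master seed, replicate, chromosome), keeping them
  distinct, reproducible and below 2³¹.

Output is a documented text encoding of the genealogy — node, edge, site
and mutation TSV tables with 0-based half-open bp intervals — plus VCF 4.2
for the variants. The native binary tree-sequence format of established
tskit-based pipelines is deliberately out of scope; the tables carry the
same information in a form that is diffable and trivially parseable.

## Analytic coalescence-rate curves

For two lineages sampled from given demes, the pair-location distribution
p_{ij}(t) over unordered deme pairs evolves under a master equation:
migration moves one lineage at a time between pair states and coalescence
drains the same-deme states at 1/(2Nᵢ(t)). The instantaneous pairwise rate
is λ(t) = Σᵢ p_{ii}(t)/(2Nᵢ(t)) / P(T > t) and the inverse-size curve is
1/(2λ). Lineage-move events transform the state vector instantaneously
(each lineage relocating independently).

Numerics: epochs with zero growth are advanced by matrix exponentials
(exact); growth epochs use adaptive high-order explicit stepping (DOP853,
rtol = atol = 10⁻¹⁰). Curves are left-continuous step evaluations at grid
points, matching the binning of the empirical hazard estimator. Where
λ(t) = 0 (e.g. two demes before their split, with no migration) the inverse
size is reported as infinity, not clipped.

The empirical counterpart bins Monte-Carlo TMRCA draws on the same grid:
rate = events / (at-risk × width). This estimator carries the usual
within-bin discretization bias of order λ·width, so validation grids keep
λ·width small; the sharper consistency check used in the acceptance
machinery compares the *event counts* per bin against their exact binomial
distribution given the analytic conditional coalescence probability —
unbiased at any bin width. Pointwise 99% bands are used wherever analytic
survival exceeds 5%; with ~40 bins checked, a rare single-bin excursion is
expected by chance and the acceptance script reports the observed count
honestly rather than suppressing it.

The independent cross-validation in the test suite compares the analytic
curve against msprime's coalescence-rate trajectory on a
bottleneck-plus-island model (agreement to 10⁻⁴ relative), keeping the
implementation and its oracle fully separate.

## Summary statistics and masking

SFS, joint SFS, π and binned r² follow their textbook definitions; π is
also tested against the SFS identity π = Σ i(n−i)ξᵢ·2/(n(n−1)) per bp. LD
excludes singletons by default (configurable), the standard practice for r²
statistics; the residual finite-sample bias level for independent sites is
≈ 1/(n−1), which the tests verify by a column-permutation oracle.

The low-recombination mask drops maximal runs of map intervals whose rate
falls strictly below the length-weighted 5th-percentile rate (so a uniform
map masks nothing). The "at least 1 cM" size criterion is deliberately
operationalized as *physical length converted at the chromosome's mean
rate* (bp × mean cM/bp ≥ min_cM): a literal genetic-length criterion could
never fire inside a low-recombination run, whereas this reading selects
exactly the large cold blocks the rule is meant to remove. The rule is
isolated in one configurable function and validated against a per-bp
brute-force scan.

## Rescaling

`rescale` divides sizes and event times by Q and multiplies all
per-generation rates (growth, migration, mutation, recombination, and the
carried selection-coefficient slot) by Q, leaving θ = 4Nμ, ρ = 4Nr and 4Nm
exactly invariant per epoch and map interval. Under neutrality the
coalescent process is identical up to the time relabeling t → t/Q, so
site-statistic distributions are unchanged; the acceptance machinery
verifies this by KS tests on π and binned r² between Q = 1 and Q = 10 runs
of the generic two-epoch model (200 replicates each, Bonferroni-controlled
at α = 0.01). The selection slot is interface-only: quantifying rescaling
artifacts under selection is out of scope.

## Synthetic data and what the tests do and do not show

No external downloads are used anywhere. Genetic maps are either uniform,
parsed from user-supplied HapMap-format text, or synthesized as equal-width
windows with i.i.d. log-normal rates (defaults: median 10⁻⁸ /bp/gen,
log-sd 1 — human-like magnitude with realistic order-of-magnitude
heterogeneity). The synthesizer reproduces rate heterogeneity but not the
spatial autocorrelation, hotspot punctuation or telomere/centromere
structure of real maps; masking and distance computations are therefore
validated on its output as *interval arithmetic*, and conclusions about
real maps rest on the format parser, not on the synthesizer. Likewise the
demo catalog ships a single synthetic species (`GenSpe`) with generic
models; real published models enter through model-definition files and the
QC equality workflow, and their numeric parameters are deliberately not
hard-coded.

Validation problem sizes (10⁵ single-locus TMRCA replicates per reference
scenario, 10³ replicate loci for the neutral closed forms, 200 replicates
per arm for the rescaling comparison, 50-kb contigs with n = 10 samples)
were chosen so the whole validation surface runs in about a minute on one
core while keeping Monte-Carlo standard errors a small fraction of the
tolerances tested.

## Known limitations

* Only piecewise-exponential epoch dynamics are representable; continuous
  size functions must be discretized by the user.
* No selection, gene conversion, or multi-chromosome linkage; ploidy enters
  only at VCF pairing time.
* The engine is pure Python: comfortable at the tens-of-kb to few-Mb scale
  used for method benchmarking, not at whole-genome-biobank scale.
* The hazard estimator's within-bin bias (documented above) means coarse
  grids systematically overestimate inverse sizes; use the binomial
  band check or finer grids for quantitative comparisons.
* k-lineage (k > 2) coalescence-rate curves are not computed.
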
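# Methods

`apmsnet` re-creates, as a tested pipeline on synthetic data, the
computational route from replicated tandem-affinity-purification
mass-spectrometry (TAP-MS) spectral counts to a confidence-annotated
protein-interaction network, plus a ribosome-footprint check of a gene's
translation start. This note documents the models, the defaults and why,
what the generators do and do not emulate, and the numerical choices.

## Interaction scoring

The published analyses this pipeline follows delegate scoring to SAINT,
described there only as assigning "the probability of observing a true
interaction using Poisson distributions". SAINT's full hierarchical-Bayes
model is not reproduced here; the scorer is a concrete, documented
two-component Poisson posterior:

* **Background rate** λ_f of a prey, when scoring bait *b*: the prey's
  total count over all no-bait control runs and over all purifications of
  baits other than *b*, plus a pseudocount (default 0.5), divided by the
  number of those purifications plus the same pseudocount. A floor of 0.01
  guards preys absent everywhere. The purification universe is inferred
  from the filtered tables (a purification whose records are all removed by
  filtering drops out).
* **Foreground rate** λ_t of a pair: the mean of its replicate counts,
  floored at `min_enrichment · λ_f` (default 2) so that weak pairs cannot
  collapse λ_t onto λ_f and render the posterior unidentifiable.
* **Posterior** per replicate with count *x*, prior π (default 0.1):

      p = π·Pois(x|λ_t) / [π·Pois(x|λ_t) + (1−π)·Pois(x|λ_f)]

  evaluated in log space. The pair's confidence (`avg_score`) is the
  arithmetic mean over the bait's replicates; a replicate in which the prey
  went unobserved contributes x = 0.

Pairs with no nonzero filtered count are not scored. Scoring is
deterministic and replicate-order invariant.

Three preprocessing options form the sweep axes, applied in this order:

1. **Identification-score filter**: drop records with id score below a
   Mascot-like threshold *m*. Filtering acts per record (protein level);
   the field's search engines also score peptides, but the synthetic data
   carries protein-level scores and the choice is stated here once.
2. **High-count capping** (optional): counts above the 0.95 empirical
   quantile of all retained nonzero counts (linear interpolation, floored
   to an integer) are replaced by that quantile. "Taking extremely high
   counts into account" could equally mean down-weighting or exclusion;
   capping is this package's choice.
3. **Normalization** (optional): each purification's counts are rescaled so
   its total matches the median purification total, then rounded to the
   nearest integer, ties to even. Deterministic and scale-free.

A known limitation of the background estimator: a prey that is a true
interactor of several baits contributes its own foreground counts to the
background of each, depressing its score. In screens with very few baits
this is noticeable; at the 8-bait scale used throughout the tests it is
negligible. Likewise, when purification depths vary, a single shallow
replicate can drag a true pair's posterior mean below 0.8 under any *single*
option set without normalization; the sweep marginalizes over the
normalization axis, and single-option scoring should enable it whenever
depth variation is expected.

## Parameter sweep and robustness

The grid crosses the call threshold τ (default 0.80–0.95 in steps of 0.01,
built by integer index arithmetic so exactly 16 values appear and the 0.95
endpoint is exact), the identification threshold m (default
{10, 20, 30, 40, 50}), and the two binary axes — 320 combinations.
Scoring depends only on (m, cap, normalize), so each of the 20 distinct
option sets is scored once and τ is applied as a threshold; this is
provably identical to re-scoring per combination and keeps the full sweep
on an 8 × 200 screen around a second.

A pair is *called* in a combination when `avg_score ≥ τ` (inclusive — the
source methods say "threshold" without strictness, and inclusivity
preserves the 0.95 endpoint). Its **robustness** is calls / 320. Pairs
reaching `avg_score > 0.8` (strict, "above 0.8") in at least one
combination are *candidates*; candidates with robustness ≥ 0.5 are classed
`robust`, the rest `low`. The source is internally inconsistent about the
boundary (methods "≥0.5", figure legend ">0.5") and about the external
import threshold ("0.9" vs ">0.9"); this package follows the methods text
in both cases.

## Network assembly

Bait→prey records are directional during scoring; reciprocal observations
are merged onto unordered pairs keeping the maximum robustness and maximum
score before edges are classified. Five mutually exclusive edge classes
mirror the published figure legend: robust candidates split into
`TAPMS_SUPPORTED` / `TAPMS_ROBUST` by the presence of an
experimental-channel external edge at *any* confidence; low-robustness
candidates are `TAPMS_LOW`; non-candidates whose best score lies in
(0.7, 0.8] and that carry experimental support are
`TAPMS_MARGINAL_SUPPORTED`; pairs not observed in the screen enter only as
`EXTERNAL_ONLY` when an experimental-channel edge reaches confidence ≥ 0.9
and touches a screen node. "High-confidence TAP-MS interactions" in the
supported-edge rule is read as the robust-candidate condition, parallel to
the unsupported thick-black rule. Imported edges attach one step from the
screen by default; chaining through other imported nodes is available
behind `allow_chaining` because the source wording ("reported connections
to baits and preys") is ambiguous. Duplicate edges keep the
highest-precedence class in the order listed above. The network is written
as GraphML plus SIF with an edge-attribute TSV, with deterministic ordering.

## Anchored clusters and enrichment

Imported nodes of degree exactly 1 whose sole neighbor is a screen bait or
prey are grouped by that neighbor; the source's three manually curated
clusters are out of scope, but user-supplied clusters can be fed to the
enrichment step via `--extra-clusters`. Enrichment per cluster and term is
the one-sided hypergeometric upper tail on the overlap within a node
universe (default: annotated nodes present in the network), with
Benjamini–Hochberg correction across the terms tested within the cluster —
the minimal standard reading of "GO enrichment analysis", since test,
correction and universe are unstated in the source. Terms are opaque
labels; no ontology propagation is performed.

## Translation-start calling

Footprint read starts (5′ ends, gene strand, 0-based half-open) are binned
in fixed windows (default 30 bp). The published call was made by visual
inspection of the binned profile; the operational rule here is: scanning
candidate ATGs upstream-first (candidates at or upstream of the annotated
start are the fallback, not tested), choose the first candidate *c* whose
mean per-bin density from the bin containing *c* onward exceeds
`ratio_min` (default 5) times the mean density of the bins fully inside
[annotated_start, *c*), the upstream mean floored at one pseudoread per bin
(and equal to the floor when no full bin fits the gap). If no candidate
passes, the annotated start is reported with offset 0. Because the
downstream mean includes all signal beyond *c*, a decoy candidate placed
inside an untranslated gap between two true candidates would also pass;
candidates should therefore be actual ATG positions, which is how the
generator and pipeline use the caller. With a 36-codon skipped extension
the reported offset is 3 × 36 = 108 bp.

## Synthetic-data generators

The AP-MS generator emulates the screen the analysis assumes: counts for
(bait, prey, replicate) are Poisson with rate
`depth · background_rate · enrichment` for planted true pairs and
`depth · background_rate · present` for contaminants. Defaults are the
benchmark conditions used throughout: 8 baits, 200 preys, 4 replicates,
4 control runs, background rate 2, enrichment 10, planted density 0.05.

* **Depth factors** are log-normal with mean one (σ = 0.3 by default) per
  purification, giving the normalization axis something to correct while
  leaving expected counts at their nominal values.
* **Presence model**: 30% of contaminant preys are "sticky" and appear in
  95% of purifications, controls included; the rest appear in 35%. This
  stands in for the unknown count structure of a real no-bait control
  strain and gives the background estimator realistic sparsity. Planted
  pairs are always present, so exact exchangeability with contaminants at
  enrichment 1 holds only when presence is set uniform — the property test
  does exactly that.
* **Identification scores** grow with spectral abundance:
  `clip(5 + 4·count + N(0, 2), 5, 60)`. Search-engine protein scores sum
  peptide evidence and therefore track abundance; a background-level prey
  (~2 spectra) scores ≈ 13 and falls to every sweep threshold above 10,
  while an enriched prey clears the top threshold of 50. Independent
  uniform scores would make the identification axis remove replicates of
  true pairs at random, which no real Mascot filter does and which would
  make high sweep thresholds uninformative rather than stringent.

The evidence generator supports each planted pair with an
experimental-channel edge at probability `support_prob`, attaches
`n_imported` external nodes by one high-confidence edge each to a few
anchor screen nodes (yielding the degree-1 clusters), and adds noise edges
between random screen-node pairs — noise is confined to screen nodes so
the planted cluster structure remains under the generator's control. The
annotation generator plants one term on a chosen subset plus background
nodes at a low rate, with independent decoy terms. The footprint generator
places reads uniformly downstream of the true start except a `leak`
fraction scattered over the whole region.

What the generators do **not** emulate: peptide-to-protein inference,
bait-specific contaminant preferences, correlated replicates, carry-over
between runs, real STRING evidence-channel structure, ontology structure
among terms, and the empirical read-length/periodicity structure of real
ribosome profiling. Passing recovery tests therefore demonstrate the
pipeline's correctness under its own model assumptions, not performance on
any real screen.

## Reproducibility and problem sizes

All randomness descends from one root seed through named per-stage
`SeedSequence` substreams; identical config + seed reproduces every output
byte for byte, and any stage re-run from on-disk intermediates matches the
full run. Benchmark sizes used by the tests and the acceptance script — an
8 × 200 screen under the full 320-combination sweep for three seeds, 100
seeded draws for the Monte-Carlo checks, 20 footprint tracks — were chosen
so the entire suite completes in well under a minute on one core while
keeping every proportion estimate's binomial standard error below ~2
percentage points.

## Known limitations

* The scorer shares SAINT's structural blind spot for preys that interact
  truly with many baits (their background estimate is inflated).
* The robustness fraction treats all 320 combinations as exchangeable
  votes; no weighting by plausibility of the parameter set is attempted.
* The start-site rule is a deliberately simple operationalization of a
  visual judgment; it assumes candidates are genuine ATGs and a single
  dominant translated region.
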
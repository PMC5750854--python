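# Methods

## Scoring model

A gene's evidence is the binary vector *S = (S₁,…,S_N)* over *N* ≥ 2
categories; the combined score is the weighted count Σ wᵢSᵢ.  Weights are
constrained to the nonnegative unit simplex.  The constraint is a modelling
choice, not a loss of generality: the gene ranking is invariant under
positive rescaling of the weight vector, so normalization removes a flat
direction that would otherwise let the annealer drift without changing the
objective, and nonnegativity reflects the semantics of a source
*contributing* evidence.  With simplex weights every combined score lies in
[0, 1], which also fixes the axis of the diagnostic histogram.

## Rank objective

The only requirement on the weights is that the gold-standard core genes end
up near the top of the ranking.  We make that precise as the mean fractional
tie-averaged rank of the core genes,

    E(w) = (1/|C|) Σ_{g∈C} avg_rank(g; w) / M,

with descending-score ranking and ties assigned the mean of the positions
they occupy (the standard statistical convention; `scipy.stats.rankdata`
with `method="average"`).  Properties that drove this choice:

- scale-free in the problem size *M*, so objectives are comparable across
  datasets;
- equivalent, up to an affine map, to a Mann–Whitney-type separation
  statistic between core and non-core score distributions — no tuning
  constants;
- tie-averaging makes *E* independent of arbitrary sort stability, which
  matters because binary evidence with small *N* produces massive score ties;
- bounds: *E* ∈ (0, 1], with the minimum (|C|+1)/(2M) attained iff the core
  genes occupy the top |C| positions without ties to outside genes (the tied
  core block then averages to (|C|+1)/2).

The displayed ranking separately breaks ties by ascending gene symbol so
that output files are deterministic; `avg_rank` is carried in the output so
the objective can be recomputed from the table.

## Simulated annealing

Search starts at uniform weights 1/N.  A proposal perturbs one uniformly
chosen coordinate with Gaussian noise (sd `proposal_sd`), clips negatives to
zero, and renormalizes; an all-zero vector is redrawn.  Acceptance is
Metropolis, `min(1, exp(-ΔE/T))`, with geometric cooling `T ← c·T` after
each block of `steps_per_temperature` proposals.  The best-ever weights are
returned, so the best-objective trace is non-increasing by construction.

Defaults: initial temperature 1.0, cooling factor 0.95, 50 steps × 100
temperatures (5000 proposals), proposal sd 0.1, seed 42.  The objective
landscape for binary evidence is piecewise constant with O(2^N) distinct
score patterns, so for the small *N* typical of multi-source gene evidence
(N ≤ 6) 5000 proposals reach the global basin reliably; the initial
temperature of 1.0 is an order of magnitude above typical objective
differences (which live in (0,1)), giving a genuinely explorative start.
All parameters are exposed (`SAConfig`, CLI flags) and every run is
reproducible from the seed via `numpy.random.default_rng`.

Because the landscape is piecewise constant in *w*, the optimum is a
plateau, not a point: optimal *weights* are not unique even when the optimal
*objective* is, and tests compare objectives, not weight vectors.

## Grid oracle

An independent check enumerates all weight compositions k/step on the
simplex at resolution `step` (C(1/step + N − 1, N − 1) points) and returns
the best.  It is deliberately implementation-independent of the annealer —
plain enumeration against the same objective — and the annealer must never
be worse than it (the continuum contains the grid).  Intended for N ≤ 5 and
step ≥ 0.05.

## Threshold policies

The method leaves the prioritization cutoff to the user, guided by two
diagnostics.  Three explicit policies are implemented: `top-k:K` (flag the K
best ranks), `score-cutoff:S` (flag scores ≥ S), and `cover-core:Q`
(smallest score threshold flagging at least a fraction Q of the core
genes); default `cover-core:1.0`.  Core genes remain in the ranked output,
flagged `is_core`, since the score-distribution diagnostic explicitly
overlays core vs all genes.

## Diagnostics

`score_distribution` bins combined scores into `n_bins` equal-width bins on
[0, 1] (last bin right-inclusive, the `numpy.histogram` convention); the
default of 20 bins resolves the ≤ 2^N distinct score levels reachable at
small N.  `threshold_curve` reports, per display rank, the score and the
running count of core genes, i.e. the dual-axis rank curve.  Both are plain
tables; PNG rendering is a thin optional layer and is not asserted beyond
file creation.

## Literature co-occurrence screening

Gene–topic relatedness is screened by document co-occurrence.  For each
gene, every alias is crossed with each topic phrase (defaults: nicotine,
nicotinic, tobacco, smoking); a pair "hits" a document when the document
text contains both terms as case-insensitive whole-word token matches
(tokens split on any non-alphanumeric character, so hyphens separate;
multi-word symbols match as contiguous token runs; no stemming, no fuzzy
matching — transparent and deterministic rather than search-engine
faithful).  Per-pair counts are pooled by plain summation across aliases
and phrases, mirroring the convention of summing separate per-query hit
counts; a document naming two aliases is therefore counted once per pair.
Because that convention can double-count, the deduplicated distinct-document
count is always reported alongside (`distinct_hits`), together with the
matched document ids so the manual-review worklist is actionable.  Triage
on the pooled total: ≥ `min_hits` (default 5) auto-include, 1 to
`min_hits`−1 manual review, 0 excluded.  The manual review itself is human
curation and out of scope.

## Evidence-file handling

Upload format: comma-delimited UTF-8 CSV with a mandatory header, ≥ 3
columns (≥ 2 sources plus the core column last).  Ragged rows are the
normal case for gene lists of unequal length and are accepted; empty cells
are skipped; duplicate symbols within a column collapse.  Symbols are
normalized (uppercase, trimmed, internal whitespace collapsed) and matched
exactly — alias expansion belongs to the screening layer, not here.
Duplicate category names are rejected because weights are keyed by name.
A core gene appearing in no source column contradicts the "at least one
element is 1" matrix property; it is kept with an all-zero row, a
`CoreCoverageWarning` is emitted, and it still counts in the objective —
silently dropping gold-standard genes would bias the optimized weights
toward whatever remains.

## Synthetic data

`gen_evidence_matrix` draws each indicator Bernoulli(pᵢ) with per-category
background rates, boosted (capped at 1) for a designated core subset — the
planted structure the prioritizer assumes: informative categories enrich
true genes.  All-zero rows are repaired by switching one uniformly chosen
category on, rather than rejection sampling, so generation always
terminates; note the repair inflates low-rate columns (at background rates
around 0.1 with several categories, a substantial fraction of rows is
repaired), so column sums match n·p only where the all-zero probability is
small — tests of rate fidelity use high-rate settings.

`gen_corpus` emits exactly the planted number of documents per
(alias, phrase) pair — each document contains that alias, that phrase, and
filler words drawn from a fixed vocabulary screened against all alias and
phrase tokens — plus pure-filler noise documents.  Hence whole-word counts
on the generated corpus recover the planted table exactly, making screening
tests assertions of equality rather than probability.  The generator makes
no attempt at realistic abstract language, citation structure, or the MeSH
expansion and field weighting of a real retrieval engine; passing tests
certify the counting/pooling/triage machinery, not retrieval fidelity on
real literature.

## Problem sizes

Default verification sizes — 300–500 genes, 3–4 categories, 20–30 core
genes, 20–25 seeded replicates, 200-gene screening corpora — are the scale
at which the planted structure is unambiguous while the exhaustive grid
oracle (231 points at N=3, step 0.05) remains exact; real uploads of a few
thousand genes run in seconds since each objective evaluation is one
matrix-vector product plus a ranking.

## Known limitations

- The objective treats all core genes equally; no confidence weighting of
  the gold standard.
- With few categories many genes share a score; the ranking within a tied
  block is alphabetical, not evidential.
- Pooled hit totals conflate evidence strength with alias count; use
  `distinct_hits` when that matters.
- No gene-identifier resolution beyond symbol normalization (no Entrez IDs,
  no species handling, no live database queries).
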
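# Methods

## Scope and model

The package implements a proteome-to-drug-combination analysis chain
for two-group label-free proteomics. The scientific object at each
stage:

* **DE calling.** Fold change is the ratio of linear-scale group means;
  the test is Welch's unequal-variance t on log2-transformed
  intensities. A protein is DE iff |log2 FC| ≥ log2(fc_threshold) and
  p < alpha. The published protocol this follows names neither the test
  statistic nor the transform; Welch-on-log2 is our documented choice —
  robust to unequal group variances at n = 10 per group, and standard
  for intensity data whose noise is multiplicative. Raw p-values are
  used deliberately (no multiple-testing correction), matching the
  discovery-oriented filter the pipeline reproduces; this inflates the
  family-wise error and downstream stages must be read accordingly.
* **Interaction scores.** Score(compound, protein) =
  max over the protein's predicted binding sites of
  PScore × Dice(compound fingerprint, site template ligand). The
  aggregation over multiple sites is the module's one free parameter
  (`max` default, `mean`/`sum` available); `max` reads as "the best
  site dominates binding likelihood" and keeps scores in [0, 1] given
  PScore ∈ [0, 1] (enforced on input). The winning site and its two
  factors are recorded per entry.
* **Consensus ranking.** For each known-treatment drug the other
  compounds are sorted by cosine similarity of signatures (descending),
  ties broken lexicographically by compound ID so the output is
  deterministic and invariant to input order. Known drugs stay inside
  each top-k list (they consume slots) but are never credited as
  candidates; `exclude_known_from_lists=True` frees their slots.
  Candidates are ordered by (consensus count desc, average within-list
  position asc, ID asc). "Average rank" is the mean of within-list
  positions.
* **Betweenness and hubs.** Unweighted betweenness with endpoints
  excluded, unordered pairs, unreachable pairs contributing zero —
  computed with the Brandes implementation in networkx
  (`normalized=False`) and cross-checked in the test suite against an
  independent brute-force oracle that enumerates every shortest path
  (BFS distance layers + backward path expansion). Literature reference
  counts are stored on edges but never used as weights. Edges are
  undirected by default (`directed=True` available on graph build).
  Hub rule: Cb/max(Cb) ≥ 0.25 is primary; a secondary `gap` rule cuts
  the sorted profile at its deepest drop exceeding the linear baseline
  (range/(n−1)) — the published phrasing of the gap criterion is
  ambiguous, so both are shipped and the fraction-of-max rule is the
  default.
* **Enrichment.** Sc is computed as D·M/√(‖D‖²‖M‖²) — one square root
  of the squared-norm product, so D = ±M returns exactly ±1 in floating
  point. Combination nulls match combination size (size-k observed
  scores vs size-k background combinations) on exchangeability grounds.
  Null enumeration is exhaustive when the number of combinations is at
  most `n_null_samples` (default 10,000), otherwise uniformly sampled
  with a fixed seed. Ties in the null are *not* counted in r ("strictly
  greater"), which makes p̂ = (r+1)/(n+1) conservative; its minimum is
  1/(n+1) by construction. Combinations whose net effect cancels to
  the zero vector have no direction to score: they get Sc = NaN, are
  never significant, and sort last. Report ordering is Sc desc, p̂ asc,
  size asc, members lex. No correction across combinations is applied
  by default. Drug frequencies count each member of every significant
  unordered pair once, so counts sum to twice the number of significant
  pairs.

## Synthetic study

The generator emulates the five inputs of the real analysis with
planted, verifiable truth:

* **Intensities** are log-normal: per-protein baseline log2 abundance ~
  U(16, 26), within-group noise normal on the log2 scale with sd
  matched to the linear coefficient of variation
  (σ_log2 = √ln(1+CV²)/ln 2). Planted DE proteins (half up, half down)
  get a group-mean log2 shift of exactly ±`log2_effect`. Defaults —
  n = 10 per group, 40 DE of 200 proteins, log2 effect 2, CV 5% — are
  the benchmark conditions used throughout the tests. A per-sample
  recovery factor (`recovery_cv`, default 0) multiplies every protein
  including the constant-concentration albumin row, so albumin
  normalization removes it exactly; zeros can be injected via
  `missing_fraction` (default 0).
* **Compounds** are random bit vectors (128 bits, density 0.15 by
  default; a drawn-empty fingerprint gets one random bit). One
  non-known compound is a bitwise *clone* of the first known drug.
  Real chemistry fingerprints can be plugged in; the scoring modules
  only see bit vectors.
* **Binding sites**: 1–3 sites per library protein, PScore uniform on
  (0, 1], random template ligands. The library covers
  `n_de_in_library` of the planted DE proteins (default
  min(30, n_de_true)) plus non-DE proteins up to `n_library_proteins`,
  so the "DE proteins without structural coverage" report is exercised.
* **Regulatory graph**: the non-isolated DE proteins form
  `n_hub_planted + 1` clique communities chained by the planted hubs;
  hub *i* is adjacent to every member of communities *i* and *i+1* and
  communities share no other vertex, so all cross-community shortest
  paths pass through hubs and the planted hubs provably dominate
  betweenness (re-verified per generated graph by the brute-force
  oracle in the tests). A configured fraction of nodes stays isolated.
  Cliques rather than preferential attachment trade realism for
  certain ground truth.
* **Drug effects**: the *ideal* drug is the clone compound and carries
  exactly the idealized signs on the hubs — being the clone guarantees
  it survives the consensus-ranking stage (it is position 1 in its
  template's list), so the end-to-end run can assert it tops the
  enrichment report. The *anti-ideal* drug carries all signs flipped.
  Background drugs get 1–4 random signed effects on random connected
  entities.

What passing tests on this generator do **not** show: robustness to
missing-not-at-random intensities, peptide-to-protein rollup error,
correlated fingerprints within chemical classes, scale-free regulatory
topology, or curation noise in effect signs. The generator's role is to
make each algorithmic contract falsifiable, not to simulate biology.

## Numerical and degenerate-input choices

* Proteins whose case or control mean is zero get no finite ratio: they
  are excluded from calling and listed (no pseudocount by default).
* Rows constant in both groups give a 0/0 t statistic; their p-value is
  reported as 1 (no evidence against the null).
* An optional `min_evidence` column filter implements the strict
  two-peptide identification criterion; default is the pragmatic
  one-peptide mode.
* Zero-vector signatures similarity = 0 with a warning in ranking;
  zero effect vectors are ineligible for enrichment (error for
  candidates, dropped from nulls).
* All randomness flows through `numpy.random.default_rng` seeded from
  the config; generator streams are keyed `(seed, stream_id)` so each
  input is independently reproducible and a rerun is byte-identical.

## Problem sizes

Default test-scale studies use 200 proteins, 120 compounds and a
40-node graph. The full-dimension smoke configuration — 2450 compounds,
34 known treatments, a 500-protein structure library with a 130-protein
signature subset, and a 214-node graph with 112 isolated nodes — runs
end to end in well under a minute on one CPU; these sizes mirror the
study the pipeline is modeled on and are the package's standard large
benchmark.

## Known limitations

* The consensus protocol's behaviour when known drugs tie with
  candidates at identical similarity depends on the documented ID
  tie-break; with many identical signatures the ordering is
  deterministic but arbitrary.
* At equal Sc the report prefers smaller p̂, so a two-drug combination
  that exactly reproduces M can precede the single ideal drug when its
  (larger) null grants a smaller attainable p̂.
* The empirical p-value is bounded below by 1/(n+1); with small
  exhaustive nulls (few background drugs) no combination can reach
  conventional significance, which is a property of the data, not a
  defect.
* Directed-graph betweenness is available but the default undirected
  treatment discards regulation direction, as the unweighted published
  analysis did.
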
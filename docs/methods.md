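# Methods

This note records the models implemented in `herbnet`, the parameters that
matter, the numerical conventions, and the design choices made where more
than one reasonable option existed. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The interactome and distances

The interactome is an undirected, unweighted graph over protein symbols.
Loading removes self-loops and merges duplicate edges (counts are logged);
an optional many-to-one identifier map is applied first, and rows with
unmapped identifiers are dropped with a warning. All biological weight
lives on nodes — edge-weighted shortest paths are deliberately out of
scope.

Distances are exact unweighted shortest-path lengths by breadth-first
search. An unreachable pair is carried as an explicit marker, never as a
substitute finite distance: any finite stand-in would be arbitrary and
would leak into the permutation nulls. Unreachable pairs (or herb nodes
that reach no disease node, for the closest-node metric) are dropped from
numerator and denominator alike, identically in observed and null
evaluations, and counted in every result record. No restriction to the
largest connected component is applied; dropping unreachable pairs covers
the same ground without silently discarding nodes.

## Evidence integration (disease side)

Quantitative sources are min–max scaled into [0, 1]; exact zeros are lifted
to `epsilon_zero` = 1e-5 because a zero would annihilate the multiplicative
product. Sources already normalized to [0, 1] (DisGeNET-style) pass through
unchanged apart from the same zero-lifting. A qualitative source scores
listed targets 1.0 and unlisted ones `epsilon_missing` = 1e-20; the same
1e-20 imputes targets missing from any other source under the
multiplicative scheme. The gap of fifteen orders of magnitude between the
two epsilons is intentional: absence from a source is treated as far
stronger counter-evidence than a minimal observed score. Literature-mining
mention counts are normalized by the maximum count.

The multiplicative integration is a consensus filter — a target must be
supported by every source to rank highly. The additive alternative (sum,
missing imputed as zero) is retained for comparison;
`compare_rankings` reports Jaccard overlap of Top-N sets and the Spearman
correlation of ranks over the union of the two Top-N sets (midranks for
ties; a union member absent from one table gets that table's worst rank
plus one — the comparison domain is otherwise undefined).

Top-N selection orders by descending score with ascending-symbol
tie-breaking, for reproducibility. The selected scores are rescaled into
(0, 1] by the same smoothed max–min mapping used on the herb side, giving
the disease-side node weights; the weighted proximity needs both sides in
(0, 1] and the integrated products would otherwise live on absurd scales
(down to 1e-100).

## Herb weighting

`W_j = Σ_h Σ_c R_h · A_{c,h} · P(c,j)`, accumulated over every
(herb, compound, protein) triple in the catalog. Method 1 sets A = P = 1,
method 2 sets P = 1, method 3 uses everything. Two conventions deserve
note:

* Under method 1 the literal accumulation counts an herb once per
  interacting compound (compound multiplicity matters). A
  `once_per_herb` switch gives the alternative reading — each herb
  contributes R_h at most once per protein — because "weights from dosage
  ratios alone" is genuinely ambiguous between the two.
* Abundances are used as given, with no per-herb renormalization; callers
  who want within-herb relative abundances to sum to 1 should pre-normalize.

Normalization into (0, 1] is `(w − min)/(max − min) · (1 − ε) + ε` with
`epsilon_norm` = 1e-6: the minimum maps to exactly ε, the maximum to
exactly 1, and the map is invariant to positive rescaling of the raw
weights. A degenerate profile (all raw weights equal) is mapped to uniform
1.0 with a warning rather than to ε — a uniform profile carries no ranking
information, and collapsing it to ε would asymmetrically crush weighted
products.

A single-compound drug is represented as a one-herb formula with R = 1,
A = 1 and catalog confidences for its targets, so drugs and formulas flow
through the same machinery. Combining two interventions takes the union of
their protein sets, keeping the larger weight on overlap (the stronger of
two lines of targeting evidence); max rather than sum keeps the result in
(0, 1] and is idempotent.

## Metrics

Five metrics, two conventions worth stating:

* The closest-node proximity is implemented exactly as
  `(1/|H|) Σ_h min_d dist(h,d)` — the average over the herb side of each
  herb protein's distance to its nearest disease protein. The all-pairs
  mean (the uniform-weight limit of the weighted metric) is offered as an
  `all_pairs` variant for sensitivity checks; the two are distinct
  statistics and are never conflated.
* The weighted proximity divides the weight-scaled distance sum by the
  summed weight products of the same reachable pairs, so strictly positive
  weights guarantee a defined value whenever any pair is reachable.

## Permutation nulls and Z-scores

Null sets replace the herb side; the disease module stays fixed (the
convention in drug–disease proximity work; the herb side is the
intervention under test). Sampling is degree-aware: nodes are partitioned
into log₂-spaced degree bins, merged upward until each bin holds at least
`min_bin_size` nodes (default 100), and each reference node is replaced by
a uniform draw (without replacement within a null set) from its own bin.
Each sampled node inherits the weight of the node it replaces, so the
weight multiset — and hence the scale of the weighted metric — is
preserved under the null.

Z = (S_obs − μ_rand)/σ_rand with the n−1 sample standard deviation over
`n_perm` = 500 permutations by default. When several metrics are
requested, all are rescored on the same null draws, making
weighted-versus-unweighted contrasts paired. Randomness flows from one
master seed through per-permutation `SeedSequence` substreams, so results
are independent of execution order and bitwise reproducible.
`convergence_curve` reports the spread of Z across independent estimates
as n_perm grows, to verify that the chosen permutation count is
sufficient.

## Perturbation sensitivity

`w_i(α) = (1−α) w_i + α r_i` with r_i uniform on the open interval (0, 1)
— the open interval keeps perturbed weights strictly positive, matching
the (0, 1] weight contract. For each α on a grid, 100 simulations by
default, each scored by the Spearman correlation (midranks) between
original and perturbed rankings. Substreams are keyed by the α *value*
(scaled to an integer) and the simulation index, so extending the grid
never changes existing draws. α = 0 short-circuits to Rs = 1 exactly.

## Synthetic benchmark instances

The generator emulates the statistical shape of the real input families so
that the full pipeline can be validated offline:

* **Interactome** — preferential-attachment (scale-free) graph; default
  2000 nodes, attachment 3. This captures the heavy-tailed degree
  distribution that makes degree-aware sampling necessary, and nothing
  more; real interactomes have clustering, community structure, and
  ascertainment bias the generator does not mimic.
* **Disease module** — a connected subgraph grown by randomized
  breadth-first expansion (default 100 nodes), with weights drawn
  Beta(2, 2) (or a truncated exponential) and rescaled into (0, 1].
  Module weights are random, i.e. deliberately uninformative about network
  position.
* **Formula inputs** — Dirichlet(1) dosage ratios over 4 herbs, 20
  compounds per herb, log-normal(0, 1) abundances, Beta(4, 2) interaction
  confidences (right-skewed, as prediction confidences tend to be), 10% of
  pairs marked validated with P = 1. Each compound–protein edge lands
  inside the module's one-hop neighborhood with probability `enrichment`
  (default 0.5) and uniformly *outside* it otherwise; enrichment 0 is
  therefore an active negative control that avoids the module
  neighborhood, not merely a uniform draw.
* **Source scores** — rank-preserving noisy copies of the module weights
  (Gaussian noise on the logit scale, default SD 0.1), per-source
  missingness (default 10%), one source rendered qualitative.

All draws come from named substreams of a single master seed, and every
written artifact round-trips bit-identically through the package readers.

Because module weights are positionally uninformative by design, passing
tests show that the machinery responds correctly to planted *topological*
signal (enrichment); they do not show that weighting improves inference on
real data, where the disease weights themselves carry structure. For the
same reason, the test that asks whether weighting sharpens the proximity
Z-score constructs explicitly informative herb weights (decaying
exponentially with distance to the module) rather than relying on the
generator's defaults, under which herb weights correlate only weakly with
module proximity and weighting mostly adds variance.

## Problem sizes and numerical conventions

Default analysis sizes used throughout the tests and the acceptance
script: 2000-node interactomes with 100-node modules for control
experiments, 400–500-node instances for null-model calibration, 500
permutations for reported Z-scores (150 inside replicated control
experiments, where the contrast is large), 100 perturbation simulations.
These sizes make the full validation run in well under a minute while
leaving every statistical contrast far from marginal.

Ties in Top-N selection break lexicographically; Spearman uses midranks;
σ_rand uses the n−1 estimator; a degenerate null (σ_rand = 0) and a
constant weight vector are hard errors, not silent zeros. Floats are
serialized at round-trip precision (`%.17g`, `float_precision="round_trip"`
on read).

## Known limitations

* The synthetic interactome reproduces heavy-tailed degrees only; results
  on real networks additionally face study bias (well-studied proteins
  have more recorded interactions), which node weighting mitigates but
  does not remove.
* The multiplicative consensus is sensitive to source missingness by
  construction: a true target absent from one source drops out of the top
  ranks. This is the intended behavior, surfaced by the acceptance
  script's Top-50 recovery number under 10% missingness.
* No multiple-testing correction is applied across formulas or Top-N
  thresholds; Z-scores are reported raw.
* The degree-binning scheme (log₂ intervals, upward merging) is one
  reasonable choice among several; `min_bin_size` trades degree fidelity
  against bin-population diversity and is exposed everywhere.
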
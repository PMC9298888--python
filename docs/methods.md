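# Methods

This note records the scientific and numerical conventions behind
`trustnet`: what is modelled, which choices were genuinely open, what the
defaults mean, and what the synthetic tests do and do not establish.

## Survey instrument and coding

The unit of observation is the directed dyad (respondent, named partner).
Respondents name up to seven partners (a name-generator question bounded by
the size of a core social layer), rate collaboration intensity on six
ordinal levels (0 "no interaction at all" … 5 "collaboration") and rate
agreement with seven trust statements per partner on a 5-point scale.

Agreement codes map to the symmetric scale −1, −0.5, 0, +0.5, +1. For
network construction only the agreeing half produces edges: 4 → weight 0.5,
5 → weight 1.0, and 1–3 → no edge. Disagreement is deliberately *not* coded
as a negative ("distrust") edge: absence of trust and presence of distrust
are distinct constructs, and the instrument measures only the former. The
combined-trust weight per dyad is the mean of the seven per-dimension
weights with absent edges counted as zero; consequently combined weights
are multiples of 1/14 in (0, 1] and the combined edge set is exactly the
union of the dimension edge sets. The collaboration layer keeps the ordinal
1–5 as weight; the lowest level is absence. A respondent who names no one
is a legal outcome and survives CSV round-trips as a single all-empty row.

Missing trust ratings are rejected by default; a lenient reader maps them
to the neutral midpoint (hence no edge), since no principled imputation is
available for a single missing relational item.

## Measures: conventions where the definitions are open

- **Node universe.** Every layer is defined over roster ∪ respondents ∪
  nominees; isolates are retained. Summary moments of the weighted
  in-degree are taken over that full universe with the *population*
  standard deviation (divide by n), so layers of equal size are directly
  comparable.
- **Betweenness** uses directed, unweighted geodesics with fractional
  shortest-path sharing (Brandes accumulation). The edge weights encode
  agreement strength — a similarity — and inverting them into traversal
  costs would manufacture an arbitrary metric, so weights are ignored for
  path finding. Counts are reported unnormalized with an optional
  (n−1)(n−2) normalization flag.
- **Clustering** is the mean local coefficient on the undirected,
  unweighted projection (Watts–Strogatz form); nodes of projected degree
  < 2 contribute zero. No directed-triangle variant is used.
- **Weighted assortativity** is the Pearson correlation, across directed
  edges and weighted by the edge weight, between the source's and the
  target's weighted in-degree: positive when highly-trusted nodes nominate
  other highly-trusted nodes. It is undefined (returned as `None`, never
  silently 0) with fewer than two edges or a zero-variance marginal.
- **Freeman in-degree centralization** divides the dispersion
  Σ(c_max − c_i) by the theoretical in-star maximum (n−1)²·w_cap, where
  w_cap is the layer's maximal admissible edge weight (1 for trust and
  combined, 5 for collaboration). An in-star at full weight scores exactly
  1, a uniform configuration 0. Observed-max normalization is available as
  a config switch but off by default, because the theoretical denominator
  keeps layers with different edge counts on one scale.
- **Reciprocity** is the fraction of directed edges whose reverse exists,
  on presence only; it is invariant under any uniform rescaling of the
  weights.

## Correlations

Item–item Pearson correlations are computed on the coded responses over
rated dyads (not on edge weights, which censor the disagreeing half; an
edge-weight mode exists as an option), with a combined column equal to the
mean of the seven codes. Collaboration is excluded — its 6-level intensity
scale is not commensurate with the agreement coding.

Cross-layer rank agreement uses Spearman correlations restricted to the
top-20 nodes of each measure, because the mass of nodes at zero cannot be
ranked meaningfully. "Top 20 in each measure" is implemented as the
*intersection* of the two top-20 sets, so both rank vectors are defined
over the same nodes (union mode is available); ties are broken by stable
node-id order before selection and handled with average ranks inside the
statistic. Only correlations with p < 0.05 are flagged as reportable; no
multiple-testing correction is applied by default (an option exists).

## Null models

**Random completion.** Each simulated respondent draws a nomination count
uniformly on {0..7} (zero included: naming no one is legal), picks that
many distinct partners uniformly, and rates every item uniformly (trust
1–5, collaboration 0–5). Networks are then built by the same coding rules.
Under this model a nomination becomes a trust edge with probability 2/5.

**Preferential attachment.** A directed growth process on the matched node
count: nodes arrive in random order, and each arrival sends its edges to
existing nodes with probability proportional to (current in-degree + 1).
The +1 smoothing keeps in-degree-0 targets reachable; as the smoothing
constant grows the choice tends to uniform (verified by a chi-square
test). The total edge budget is spread uniformly over arrivals (overflow
rolling forward) so the simulated edge count matches the observed layer
exactly, and edge weights are resampled i.i.d. from the observed layer's
empirical weight distribution. Only the topology is randomized; a
consequence worth knowing is that growth produces a DAG, so the
preferential null's reciprocity is structurally zero.

**Envelopes.** For each (layer, measure, model), the model is simulated
`iterations` times (default 1,000; at least 40 so the tail quantiles are
estimable), each iteration on an independent child stream spawned from the
master seed so runs are reproducible and order-independent. The 2.5% and
97.5% empirical quantiles (linear-interpolation/type-7 estimator) bound the
envelope; undefined simulated values are dropped with their count
reported. Calibration: when the observed data really come from the random
null, each measure's outside rate is ~5% (the suite checks [1%, 12%] over
200 replicates — the envelope is a closed interval estimated from finitely
many draws, so the rate is near, not exactly, 5%).

## Synthetic survey generator

The generator stands in for undeposited partnership survey data. Its
defaults are the study conditions: a 57-member roster with a 0.75 response
rate, two outside organizations that can be nominated (59-node universe),
and a nomination-count distribution over 1–7 with mode 5 and mean ≈ 5.1,
reflecting the core-layer size the instrument's seven-name cap is built
around.

Each dyad receives a latent 7-vector
`z = √(1−tc²)·ε + tc·a + β·mutual + μ`, thresholded at the normal
quantiles of the configured marginal Likert distribution (default mildly
agreement-skewed: 0.10/0.15/0.25/0.30/0.20, so P(edge | nomination) = 0.5).
Here:

- `ε` is multivariate normal carrying the planted inter-dimension
  correlation. The planted `rho` (default 0.55, the middle of the range
  such instruments report) refers to the correlation of the *coded
  responses*; since discretizing a normal variable to five bins attenuates
  correlation by λ² with λ = corr(Z, code(Z)) ≈ 0.96 (closed form from the
  marginal), the latent correlation is inflated by 1/λ² before sampling.
  With the affinity term folded in by total-correlation semantics,
  `rho = I` genuinely yields uncorrelated codes even with nonzero
  couplings.
- `a` is a symmetric standard-normal dyad affinity shared between
  nomination preference (softmax with scale 1.0), the collaboration rating
  (coupling 0.8 — partners you collaborate with intensely are partners you
  tend to trust) and, weakly, the trust latent (coupling 0.3).
- `β` (default 0.5) plants reciprocity three ways: respondents up-weight
  candidates who already nominated them by e^β, respondents with spare
  capacity reciprocate incoming nominations with probability 1−e^{−β}, and
  mutual dyads get +β on the latent agreement in both directions. All
  three effects vanish at β = 0; layer reciprocity rises monotonically in
  β from ~0.13 (affinity-only mutuality) through ~0.40 at the default —
  the range such partnership networks report — to > 0.85 as β → large.
  Because β adds a component shared across all seven dimensions, a nonzero
  β inflates observed inter-dimension correlations slightly above `rho`;
  recovery tests therefore plant correlations with β = 0.
- Optional newcomer clusters (≥ 2 members each) with zero cross-cluster
  affinity reproduce the isolated-subgroup pattern of members who joined
  recently and only know each other.

Ground truth (rho, mutual dyads, cluster labels, respondents) is returned
with the sample so tests never re-estimate it.

What passing these tests shows — and does not. The generator's dyads are
exchangeable given affinity and cluster; real partnerships have roles,
history and transitivity the model does not plant (its clustering
coefficient arises only incidentally). Recovery of planted correlations
and reciprocity demonstrates that the *pipeline* measures what it claims;
it does not validate the latent-normal response model as a model of real
raters.

## Problem sizes and determinism

Statistical tests run at the scale needed for their tolerances: correlation
recovery at ≥ 2,000 dyads (standard error ≈ 0.02 per entry), envelope
calibration over 200 replicates of 200 iterations, model-contrast
ensembles at 300 iterations, and oracle equivalence over 200 random
digraphs of ≤ 8 nodes where exhaustive path enumeration is feasible. Every
stochastic component takes an explicit seed; iteration streams are spawned
from a master `SeedSequence`, and a pipeline run with a fixed seed is
byte-identical across repetitions.

## Known limitations

- Name reconciliation (matching free-text organization names to the
  roster) is out of scope; identifiers are opaque, case-sensitive strings.
- The betweenness/clustering conventions above are one defensible choice
  among several (directed triangles, weight-inverted geodesics); results
  on dense, strongly reciprocated layers are insensitive at the second
  decimal, but the flags exist for sensitivity analysis.
- The preferential null matches edge count and weight marginals but not
  reciprocity (structurally zero) — an inherent property of growth models,
  to be kept in mind when reading reciprocity envelopes.
- Envelope comparisons are per-measure marginal intervals, not joint
  tests; with seven measures per layer, ~1 in 3 fully-null layers will
  show at least one flagged measure by chance.
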
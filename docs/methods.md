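# Methods

This note documents the statistical models, numerical choices and known
limitations of `factorialtx`, in the order the pipeline runs them.

## Design and data model

The experimental unit is a balanced 2×2 factorial: strain ∈ {REF, DEL} ×
copper ∈ {DEFICIENT, HIGH}, with r ≥ 2 replicate arrays per cell (default
r = 2, matching duplicate fermentations). Expression values are linear-scale
summarized intensities (dChip-style model-based indices or comparable). On
input, values ≤ 1.0 are clipped to 1.0 and counted in a sanitization report:
model-based summaries can be non-positive, and downstream log transforms and
ratio fold changes require positive values. Gene identifiers are uppercased
everywhere so that matching across expression, network, annotation, regulon
and Cq files is exact.

## Baseline normalization

Each array is rescaled multiplicatively so that its overall median intensity
equals that of a baseline array, chosen as the array whose median is the
median across arrays (lower of the two middle arrays at even counts). This is
a deliberately minimal between-array normalization — it equalizes location
on the intensity scale and nothing else; quantile or loess normalization is
out of scope because the classifier's inputs are assumed already summarized
and outlier-checked.

## Two-way ANOVA

Per gene, on log2 intensities (log transform stabilizes the multiplicative
variance of array data), the balanced closed-form decomposition is

    SS_strain = 2r Σ_s (m_s − m)²,  SS_copper = 2r Σ_c (m_c − m)²,
    SS_inter  = r Σ_{s,c} (m_sc − m_s − m_c + m)²,
    SS_error  = Σ (x − m_sc)²,

with df 1, 1, 1 and 4(r−1); F = SS_effect / (SS_error / df_error), p from the
upper F tail. The implementation is vectorized over genes; tests verify it
against an exact rational-arithmetic oracle and against an independent OLS
ANOVA implementation to 1e-9.

Degenerate genes (SS_error ≈ 0, i.e. zero within-cell variance) are flagged.
For such genes the F statistic is unbounded, so effects with positive sum of
squares receive p = 0 and effects with zero sum of squares p = 1; an entirely
flat gene therefore has all p = 1. This convention is what makes noiseless
simulated data classify correctly while keeping flat genes non-significant.

No multiple-testing correction is applied to the per-gene p-values by
default: the classification operates at per-test α = 0.05 by design, and the
type-I error of each F test is verified empirically (0.05 ± 0.01 at 10 000
null genes). A Benjamini–Hochberg layer could be added by callers that need
genome-wide error control.

## Fold changes and classification

Fold changes are ratios of linear cell means: deletant/reference at each
copper level and high/deficient copper within each strain, stored as
magnitude max(ratio, 1/ratio) with a direction (the direction is "none" iff
the ratio is exactly 1). ANOVA on log2, fold change on linear means: the log
scale is the right place for the variance model, the linear ratio is how
array fold changes are conventionally reported.

Classification precedence is interaction-first (G4 > G3 > G1/G2): a gene
with a significant interaction is copper-dependent in its deletion response
by definition, so the marginal main effects are not interpreted. The
fold-change gate accepts *any* qualifying contrast of the relevant factor
(for G3, either copper level for the deletion contrast and either strain for
the copper contrast); a strict mode (`g3_gate="both"`) requires both. When a
G3 gene's two same-factor contrasts disagree in direction, the subgroup
direction is the sign of the mean of the two log-ratios and the gene is
flagged `direction_inconsistent`.

### Recovery power at the default simulation conditions

With effect size 1.0 log2, replicate noise sd 0.25 log2 and r = 2, the
strain/copper main-effect tests have noncentrality λ = 2·1/0.0625 = 32 and
exact power 0.984 at α = 0.05 (F with df 1, 4), but the interaction test has
λ = 0.5/0.0625 = 8 and power only 0.572 — four error degrees of freedom are
simply few. Exact-label recovery of a planted class additionally requires
retaining the null on the other two tests (0.95 each) and passing the
fold-change gate (≈ 0.998), so expected recovery is ≈ 0.89 for G1/G2,
≈ 0.91 for G3 subgroups and ≈ 0.56 for G4; the empirical rates agree. This
is an honest property of the design at these settings, not an implementation
artifact: at zero noise recovery is exactly 100 %, and the noise default was
chosen as a realistic replicate sd for summarized array data, not tuned for
test outcomes.

## SOM clustering

Interaction-effect (G4) genes are clustered with a classic online Kohonen
SOM: 2×3 rectangular grid (6 units — one per expected profile archetype over
4 design cells), 500 epochs, initial learning rate 0.5 and neighbourhood
radius 1.5, both decaying linearly to zero, Gaussian neighbourhood kernel,
prototype initialization by sampling data rows. Input profiles are the four
design-cell means of log2 expression, z-scored per gene so that shape, not
level, drives the clustering; a flat profile z-scores to the zero vector.
All randomness (initialization, presentation order) comes from one seeded
generator, so assignments are bit-reproducible. The hyperparameters are
package defaults — small grid SOMs are insensitive to them for
well-separated archetypes, which tests confirm (ARI = 1.0 at perturbation
sd 0.05); for genes near cluster boundaries the assignment is
seed-dependent, as with any SOM.

## Hypergeometric enrichment

The test statistic is the exact inclusive upper tail P(X ≥ k) for
X ~ Hypergeometric(N, K, n), computed by log-gamma evaluation of each
binomial term and a log-sum-exp over the tail (stable at genome scale, and
verified against exact rational enumeration to 1e-12). Terms outside the
support are handled explicitly: k at or below max(0, n−(N−K)) returns
exactly 1, k above min(n, K) returns 0. A `strict=True` option returns the
exclusive tail P(X > k) — the convention of MATLAB's `1 − hygecdf` — because
published worked examples computed that way; the inclusive tail is the
statistically standard definition and the package default. One-sided
over-representation only; depletion is out of scope.

Annotation enrichment uses a flat gene → term map with no ontology-graph
ancestor propagation. Tools that propagate annotations up the GO graph will
report different term-level results on real GO data; this is a documented
limitation, not a bug. The Bonferroni multiplier is the number of terms
actually tested (terms with ≥ 1 annotated query gene); the universe defaults
to the genes on the expression matrix and is configurable, since published
analyses vary between whole-array and annotated-subset universes.

TF-regulon enrichment restricts both the population and the query to genes
with at least one documented regulator (after intersecting with the
transcriptome universe), uses each TF's target count inside that population
as K, Bonferroni-corrects over the TFs with ≥ 1 target there, and screens at
corrected p < 1e-4. The null behaviour is verified: with no planted overlap,
≤ 1 false-positive TF per 100 seeded runs.

Shell enrichment takes an explicit background population that need not
contain the tested shell, so recipes that test a subnetwork shell against a
different network's shell population are expressible. Hits in the shell are
capped at the background's annotated count to keep the counts consistent.

## Network analysis

Edge lists are collapsed to a simple undirected graph: self-loops dropped
(nodes kept), parallel records merged with the union of their
interaction-type labels (negative/positive genetic, synthetic lethal,
synthetic growth defect, dosage lethality, synthetic rescue, other). Types
never weight edges; distance is unweighted shortest-path length. BFS shells,
connected components and induced subgraphs delegate to networkx and are
verified against Floyd–Warshall / union-find / edge-filter oracles on random
graphs. All shortest paths between two nodes are enumerated from the BFS
predecessor DAG in lexicographic node order, truncated with a flag at
`max_paths` (default 10 000) since equal-length path counts can explode.

## qPCR

Housekeeping stability is the coefficient of variation (sd/mean) of linear
expression across all arrays, ranked ascending with lexicographic
tie-breaks. CV is the simplest defensible stability metric for selecting a
normalizer panel from array data; geNorm-style pairwise variation is a
possible alternative not currently implemented. ΔΔCq follows the
comparative-Ct convention with one deliberate quirk preserved from the
source protocol: the geometric mean is applied to the housekeeping *Cq
values themselves* (geNorm convention would apply it to relative
quantities); since Cq is already a log-scale quantity, the geometric mean of
Cq values is not the same as arithmetic averaging, and the difference is
small but real. Technical replicates are averaged arithmetically on the Cq
scale before any Δ; biological samples within a condition are pooled
mean-of-means (per-pair pairing across strains is not attempted because
pairing metadata is generally unavailable). FC(A,B)·FC(B,A) = 1 by
construction.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
validated; all are deterministic given a seed, and one global seed spawns
per-component child streams (CRC-mixed, < 2^31).

* **Expression**: per gene, log2 x = baseline + a·I[del] + b·I[hi] +
  c·I[del]·I[hi] + ε, ε ~ N(0, sd), emitted as 2^(log2 x). Class sign
  patterns: G1 a = ±e; G2 b = ±e; G3.1–G3.4 the four (a, b) sign
  combinations; G4 c = ±e; NULL all zero. Defaults: e = 1.0 log2, sd = 0.25
  log2 (the source arrays' replicate variance is unpublished; 0.25 log2 is a
  typical replicate sd for summarized two-channel-free array data),
  baseline 10 log2, r = 2, class mix 72 % null. Noise sd = 0 is allowed for
  closed-form round-trip tests.
* **Network**: Erdős–Rényi at the requested density, relabelled with a focal
  node, repaired to connectivity with one bridging edge per extra component
  (the minimal repair); edge types drawn uniformly from the genetic
  vocabulary. The annotation term is planted Bernoulli(rate_in_shell) inside
  the chosen BFS shell of the focal gene and Bernoulli(rate_background)
  elsewhere. An explicit graph override supports worked examples (path
  graphs etc.). ER is the simplest connected null; it does not reproduce the
  heavy-tailed degree distribution of real interaction networks, so planted
  shell recovery demonstrates correctness of the machinery, not performance
  on scale-free topology.
* **Regulons**: every TF regulates a uniform random gene subset; the query
  contains round(overlap · query_size) planted targets (capped at the
  regulon size), remainder uniform — at overlap 0 the query is a pure null
  draw.
* **Cq tables**: the generator is the analytic inverse of 2^−ΔΔCq — a
  planted deletant/reference ratio FC shifts the deletant's Cq by −log2 FC;
  housekeeping genes are constant across conditions (plus fixed per-gene
  offsets); optional Gaussian jitter on every measurement; emitted values
  clipped to the instrument range [0, 45] cycles.

What passing these tests shows: the statistics, gates and graph machinery
are correct, calibrated and reproducible. What they do not show: robustness
to probe-level artifacts, batch effects, unbalanced designs, scale-free
network topology or annotation-graph structure, none of which the
generators emulate.

## Pipeline

Stages always write their intermediate TSVs (so any stage can be re-run or
inspected), each with a header comment recording thresholds and seed. The
manifest echoes the config, package version, seed and input checksums.
Output bundles are byte-identical across runs of the same config and seed.
A stage failure removes the partial bundle and reports the stage name. The
CLI exits 0 on success, 1 on usage/configuration errors, 2 on data errors.
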
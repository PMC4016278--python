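# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `netmark`.

## Study design and data model

The pipeline targets a two-group expression study: a genes × samples
intensity matrix (microarray-style, positive linear-scale values), binary
case/control labels, an interactome given as unordered gene-symbol pairs,
and gene sets in GMT format. All statistics run on the log2 scale after
global normalization; the scale is tracked by a tag on the matrix container
and enforced (a log2 matrix cannot be normalized or log-transformed again).

Preprocessing order is fixed: probe → gene collapse by per-sample
arithmetic mean (probes without a gene mapping are dropped and counted),
then each array is rescaled so its mean signal equals 100 (the target is
configurable), then log2. Probe averaging happens on the linear scale
before the log transform. Zero or negative intensities are rejected rather
than floored.

## SAM-style differential expression

For gene *i* with group sizes n1 (case), n2 (control):

    d_i = (x̄_case,i − x̄_ctrl,i) / (s_i + s0)
    s_i = sqrt((1/n1 + 1/n2) (SS_case,i + SS_ctrl,i) / (n1 + n2 − 2))

With s0 = 0 this is exactly the equal-variance two-sample t statistic
(verified against an independent implementation in the tests). The fudge
factor s0 stabilizes low-variance genes; by default it is estimated by
coefficient-of-variation minimization: candidates are percentiles of s
(0–100 in steps of 5), genes are binned into up to 100 equal-occupancy
bins by s, the spread of d within each bin is measured by a scaled MAD
(×1.4826), and the candidate minimizing the coefficient of variation of
those spreads wins. `fixed` and `median`-of-s modes are available.

**Permutation null.** The null distribution of d is built by recomputing
the full d vector under case/control relabelings with the same s0 and
pooling all permuted |d| values across genes (the pooled null is what
makes small cohorts workable: 10v10 gives 1,000 relabelings × 2,000 genes
= 2·10⁶ null draws rather than 1,000 per gene). When C(n, n1) ≤ n_perm
the relabelings are enumerated exhaustively — deterministic and
seed-independent — otherwise n_perm distinct relabelings are sampled
without replacement. P-values use the add-one convention

    p_i = (1 + #{|d*| ≥ |d_i|}) / (1 + n_perm · n_genes)

so p is never 0. In exhaustive mode the permuted statistics are computed
through the same code path as the observed ones, so the identity labeling
reproduces d_obs bit-for-bit and enumeration oracles agree exactly; the
Monte-Carlo path uses a faster matrix-product formulation.

Benjamini–Hochberg (step-up) correction is applied across genes and genes
are called at q < 0.01. This pairing — permutation p-values plus BH —
follows the workflow being reimplemented; canonical SAM instead reports a
median-false-positive-count FDR per |d| cutoff, which is available as an
optional cross-check column (`call_degs(..., sam_fdr=True)`).

Direction is the sign of the case−control mean difference on the log2
scale, consistent with the sign of the phenotype correlation below.

## Phenotype correlation and intersection

Each gene's expression vector is correlated with the phenotype encoded
control = 0, case = 1 (Pearson on a binary covariate = point-biserial).
Genes with |r| strictly greater than 0.8 are phenotype-related; the strict
inequality matches the stated cutoffs (r > 0.8 or r < −0.8), so r = 0.8
exactly is excluded. Zero-variance genes get r = 0 with a logged warning
rather than NaN, keeping the pipeline total. Phenotype-related genes are
intersected with the significant DEGs; phenotype-related genes that are
*not* DEGs are reported separately (in the motivating study exactly one
such gene appeared), never silently dropped.

## PPI subnetwork and hubs

Edges are canonicalized (lexicographic order, self-loops dropped,
duplicates collapsed), restricted to pairs whose both endpoints are in the
matrix, annotated with the Pearson correlation of the two profiles across
**all** samples (cases and controls pooled — pooling is what lets
disease-covarying interactors pass), and filtered at |r| > 0.8 (strict).
The network is the edge-induced subgraph over the phenotype-related DEGs:
by default an edge survives only if **both** endpoints are in the list
(`endpoint_rule="any"` is available since the describing text is
ambiguous); nodes are the union of surviving endpoints, so every node has
degree ≥ 1 and the handshake identity Σdeg = 2|E| holds by construction.
Hubs are nodes ranked by descending degree — the minimal definition
consistent with how hub genes are reported — with deterministic
lexicographic tie-breaks. Export formats are SIF and GraphML (with degree
and r_edge attributes) for Cytoscape-class viewers.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P[X ≥ overlap] with X ~ Hypergeometric(N = |universe|, K = |set ∩
universe|, k = |list ∩ universe|), BH-corrected within each invocation
(the all/up/down lists are separate invocations), significant at
FDR < 0.05. The universe defaults to all genes in the expression matrix
and is overridable. This is a plain exact test, *not* DAVID's jackknifed
EASE score; FDR values from DAVID-era analyses are therefore not
comparable at the third decimal and are not reproduction targets.

## Clustering validation

Samples (and genes) are clustered agglomeratively on the signature subset
(the network's node genes): gene rows standardized to mean 0 / sd 1,
correlation distance (1 − Pearson), average linkage — the community norm
for expression heatmaps; euclidean distance and complete linkage are
available. The sample dendrogram is cut into two branches and scored by
purity (fraction of samples in each branch matching the branch's majority
phenotype; 1.0 = perfect separation). The gene dendrogram's two-branch cut
is annotated up/down by the sign of the mean case−control difference per
group. Distance ties are broken by input order (SciPy convention); on
generic (tie-free) data the trees and scores are input-order invariant,
which the tests check. Constant vectors under correlation distance are
assigned distance 1 (maximally uninformative) rather than NaN.

## Synthetic generator

The generator emulates the targeted study at test scale and returns the
planted truth. Defaults (the `SyntheticParams` dataclass): 2,000 genes,
10 vs 10 samples, 200 DE genes, effect ±2.0 log2 units, noise sd 0.5 —
effect and noise chosen for a clearly powered design at n = 10 per group,
comparable to strong tumor/normal contrasts; 400 interactome edges with
10% co-expressed and a degree-6 planted hub; 50 gene sets of 20 genes, one
of which overlaps 15 planted DE genes.

* **Expression.** Per-gene baseline log2 abundance ~ Normal(8, 1.5);
  planted genes shifted by ±effect in the case group (half up, half down,
  odd remainder up); i.i.d. Gaussian noise on log2; intensities = 2^log2.
* **Co-expressed pairs.** Both genes' residuals are re-drawn from a shared
  latent factor with loading sqrt(0.95) (pairwise residual correlation
  0.95) — never by copying columns, which would plant degenerate r = 1
  edges. Non-DE pair genes are re-drawn around their grand mean: locking
  in a spurious finite-sample group difference would dilute the planted
  correlation.
* **Hub.** The hub is an up-regulated planted DE gene connected to
  `planted_hub_degree` other planted DE genes of either direction. Its
  residual variance is split across one latent factor per edge, each
  shared with that edge's partner with the loading sign matched to the
  partner's direction; together with the concordant/anti-concordant group
  shift every hub edge clears the |r| > 0.8 filter on the correct side.
  A single module-wide factor is deliberately avoided: it would dominate
  the samples' profiles over the group signal and corrupt sample
  clustering on the signature. The hub's residual sd is shrunk by 0.6
  relative to background genes — it is modeled as a tightly regulated
  driver, so that recovering it exercises the network stage rather than
  the sampling noise of a marginal correlation sitting at the cutoff.
* **Gene sets.** Exactly one set contains the stated number of planted DE
  genes (remainder non-DE); all other sets are uniform draws.
* **Determinism.** All randomness flows from one integer seed through
  named substreams (`SeedSequence([seed, stage_index])` with a fixed
  stage table), so stages regenerate independently and fixture bundles
  are byte-identical across runs.

What the generator does **not** emulate: probe-level cross-hybridization,
batch/array effects, intensity-dependent variance, correlated null genes,
disease-subtype structure, and literature-biased interactome topology.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under a clean planted-signal model, not calibration on real
microarray data.

## Numerical choices

* BH: vectorized step-up with a reverse cumulative minimum; input order
  restored; validated against an independent reference implementation.
* Pooled permutation counting via sort + binary search (`side="left"`, so
  ties count as ≥).
* Hypergeometric tails via the survival function of the exact
  distribution; p clamped to (0, 1] (floor 1e-300) before BH.
* Pearson correlations computed from centered sums; zero-variance rows
  map to r = 0 with a warning everywhere a correlation is emitted.
* Every ranked output (hubs, enrichment tables, DEG tables) uses
  deterministic sort keys with lexicographic tie-breaks.
* Problem sizes in tests and the acceptance script: the synthetic default
  (2,000 genes, 10v10, 1,000 permutations) per run, 20 seeds for
  Monte-Carlo rates — the scale at which the design's power is stable.

## Limitations

* The permutation null at n = 10 + 10 is pooled across genes; per-gene
  nulls are not offered (hopeless at feasible permutation counts).
* Only two-group, unpaired designs; no multi-class or paired SAM variants,
  no empirical-Bayes (limma-style) moderation, no fold-change co-filter.
* Enrichment ignores pathway topology and gene-level weights.
* The clustering stage reports a two-branch cut only; it is a validation
  readout, not a clustering method study.
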
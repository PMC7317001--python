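# Methods

This note documents the models and procedures implemented in `modminer`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Data model and input handling

All omics layers are features × samples TSV matrices with opaque,
case-sensitive identifiers; no gene-symbol normalization is attempted,
because silent symbol mapping is a classic source of irreproducible
results. Layer-specific value domains are enforced on load: methylation
betas in [0, 1], copy-number states in {−2, …, 2} (GISTIC-style
discretization is consumed, never produced), mutation calls in {0, 1}.
Missing values are never imputed: by default a missing cell is an error
naming its row and column; with `missing="drop"` (what the CLI uses) the
feature is dropped with a warning. Multi-platform layers are matched by
exact sample-identifier equality; `align_samples` restricts every layer to
the intersection in a single common order.

## Candidate selection

The variation matrix requires *joint* evidence — a somatic mutation AND a
non-zero copy-number state — before a sample counts toward a gene's
variant fraction. The >10% frequency rule is interpreted against this
joint matrix (the alternative reading, a share of all mutations
cohort-wide, would make the variant/non-variant expression contrast
ill-defined). Differential expression uses the pooled-variance Student's
*t* (Welch behind `equal_var=False`), with Benjamini–Hochberg q-values
computed over the genes that pass the frequency criterion; genes with
fewer than two samples on either side, or zero variance in both groups,
are untestable and excluded with a warning. Defaults: fraction > 0.10,
FDR < 0.01.

## Per-gene regulatory models

Each training gene's expression is modelled as a no-intercept linear
combination of its methylation, copy-number state, and the expression of
its catalogued TF, miRNA and lncRNA regulators. The training-gene list is
derived once from the tumor-vs-normal contrast (mean fold-change > 2 or
< 1/2 plus t-test/BH FDR < 0.05, a deterministic stand-in for a SAM-style
screen) and reused for both sample groups, so group differences reflect
the fits, not the gene list.

Fitting choices:

* Response and covariates are z-scored per sample group; weights are
  reported on that standardized scale (plus a de-standardized raw scale),
  which makes a single edge-retention threshold meaningful across
  covariates with very different units. Standardization also removes the
  mean, so the literal no-intercept form costs nothing.
* The model is solved by closed-form least squares. A two-layer network
  with linear activations computes exactly this function, so a
  gradient-descent trainer would add nondeterminism without adding
  expressiveness.
* Constant covariates (e.g. a CNV state that never varies within a group)
  get weight exactly 0 rather than entering the design; a rank-deficient
  design falls back to ridge regression with a logged penalty (1e−8).
* A model is fitted only when the group has at least one more sample than
  covariates; smaller groups are skipped with a warning, and a group
  smaller than `min_group_size` (default 5) is an error naming the group.

Only TF edges are thresholded into networks (default standardized
|ω| > 0.3, exposed as `--weight-threshold` since no canonical value
exists); miRNA and lncRNA terms are adjustment covariates. The
dysregulation network is the symmetric difference of the two group
networks on (regulator, target) pairs — presence only, so a sign flip
with retained magnitude does not count as dysregulation.

## Gene groups and CCRS

Group expansion reads "two-step" as graph distance ≤ 2 including the
seeds, the only reading under which a group *contains* its dysregulated
genes. Seeds are the key gene plus all dysregulation-network nodes; seeds
absent from the PPIN (non-protein entities, unmapped symbols) are dropped
with a warning, and a group with no mapped seed is empty and flagged —
mirroring the real-data situation where only part of the key genes are
reachable in the PPIN.

The corrected cumulative rank score between groups G1 and G2 with
intersection G sums over the literal four blocks (ordered pairs, including
p = q inside G). Two assumptions correct same-group pairs: a gene is at
distance 1 from itself (the distance of a direct interaction — hence
self-comparison of a connected group scores exactly 1, the minimal score
consistent with perfect self-similarity), and two connected genes of one
group count distance 1 regardless of path length. This correction is
applied to all three blocks whose pairs share a parent group — genes of G
share a group with both G1−G and G2−G; restricting it to (G, G) alone is
available via `shared_parent_correction=False` for sensitivity analysis.
Whether a path exists is decided on the whole PPIN, not the group-induced
subgraph. Path-less pairs are *excluded* from the denominator N rather
than counted as 0: counting them as 0 would make disconnected pairs
*improve* (lower) the distance. A pair of groups with no existing distance
at all is flagged absent and treated as infinitely distant by the
clustering. Defined scores always lie in [1, PPIN diameter].

## Compactness clustering

A density (DBSCAN-family) procedure over the CCRS matrix. Core points
have strictly more than `m` neighbors within ε (the point itself not
counted); clusters grow from unvisited core points by stack expansion
through *core* neighbors only — expanding through non-core neighbors
would let border points merge otherwise-separate density regions — and
border points (non-core within ε of a core) attach to the cluster of
their nearest core, ties broken toward the smallest cluster id, making
the output independent of input order. Cluster ids are canonicalized by
each cluster's lexicographically smallest member. Masked (path-less)
distances are +∞, so disconnected key genes become noise.

Automatic parameters: `m = max(2, ⌈ln n⌉)`, and ε from the sorted
m-nearest-neighbor distance curve — the knee is the point of maximum
distance to the chord joining the curve's endpoints (ties toward the
largest index), and ε is the midpoint between the knee value and the next
strictly larger curve value. The midpoint step is what places ε strictly
*between* two separated distance scales instead of on the lower one; on a
flat curve ε is the common value. Both parameters are overridable.

## Synthetic cohorts and what they show

`generate_cohort` emulates the full study design with planted truth. Scale
defaults: 150 tumor / 50 normal samples, 19 key genes in modules of sizes
8/5/6 (the module structure used as the end-to-end benchmark) plus one
deliberately module-free key gene, two target genes and four TFs per key
gene, 60 background genes, variant fraction 0.4, a 3-SD expression shift
on variant samples of key genes, 4-fold tumor/normal change on target
genes, and residual noise SD 0.1 around the regulator signal.

Mechanisms worth spelling out:

* **Dysregulation planting.** On a dysregulated TF→target edge the
  regulator acts only in the key gene's variant samples; elsewhere the TF
  sits flat at its baseline expression. Algebraically this is a
  group-switched weight on the TF's latent activity (w·z·1{variant} with
  the observed expression equal to the active signal); practically it
  makes the group-specific weight identifiable from observational fits:
  the covariate carries no variance in the non-variant group (weight 0 by
  convention) and full signal in the variant group, while any *other*
  key gene's sample split sees the edge solidly on both sides, so it
  cancels in the XOR. Stable edges carry one weight everywhere. Effect
  sizes (dysregulation weight 3, stable weight 2 on unit-variance TF
  expression) are chosen so that every retention decision sits far from
  the 0.3 threshold under the default noise.
* **PPIN layout.** A planted-partition graph: each module's TFs and
  targets form one dense block (p = 0.3), blocks are unconnected by
  default (`ppin_p_between` dials in inter-block noise), and key genes
  hang off a few private per-module background anchor nodes instead of
  sitting inside their block. Module membership is therefore *not*
  readable off the key gene's own neighborhood — it is carried entirely
  by the dysregulation network's nodes, so module recovery genuinely
  tests the omics-to-network chain, and recovery degrades as expression
  noise drowns the regulator signal (verified as a monotone trend in the
  tests). The module-free key gene's regulators live on a private island
  tied to one module through a short relay chain: its groups are far from
  every module at a finite distance, which both exercises the noise label
  and gives the k-distance curve of the ε-selection rule a well-defined
  corner. Background genes beyond the anchors stay outside the PPIN,
  standing in for genes that never map into interaction databases.
* **Marginals.** Methylation is Beta(2,5), CNV states multinomial
  (90% neutral), mutations Bernoulli; the generator makes no attempt to
  mimic real TCGA marginal distributions, mutational signatures, or
  batch structure.

Consequently, a passing benchmark shows that the pipeline's inference is
correct *when its modelling assumptions hold* — linear regulation,
group-constant weights, exact identifier matching, modular PPIN. It does
not show robustness to misspecified regulator catalogs, confounded
expression, or PPIN noise; on real cohorts the weight threshold and the
clustering parameters remain the user's responsibility.

Focused generators exist per stage: `generate_candidate_cohort` (10
planted variant genes among 200 nulls at fraction 0.3 and a 3-SD shift,
n = 100 — the candidate-filter benchmark), `generate_differential_expression`
(planted fold-change genes for the training filter), and
`make_regression_problem` (planted U(−1, 1) weights over 3 TFs, 2 miRNAs,
1 lncRNA; recovery is within ±0.1 at noise SD 0.1 and within 1e−8
noiselessly, measured against the raw-scale truth).

## Numerical and degenerate-input conventions

Pearson p-values use the t-transform with n − 2 degrees of freedom
(scipy); constant expression vectors make the correlation undefined and
the pair is skipped with a warning. No multiple-testing correction is
applied to lncRNA–gene link p-values (a raw p < 0.05 rule, matching the
screening convention for that step); the candidate and training screens
use BH. CCRS equality with the brute-force oracle is asserted to 1e−12;
the score itself is an exact rational sum, so agreement is limited only by
floating-point summation order. The acceptance script reruns every stage
from scratch under the caller's seed; simulation sizes there (50 oracle
instances per check, one full cohort) keep the whole run within a few
seconds while still exercising every code path.
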
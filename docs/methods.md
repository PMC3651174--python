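# Methods

`covmod` implements a modularity analysis of structural covariance brain
networks: graphs whose nodes are cortical regions and whose edges are
across-subject Pearson correlations of regional mean cortical thickness.
This note documents the model, the estimation and inference procedures, the
synthetic-cohort generator used for validation, and the numerical and design
choices a user should know about.

## Pipeline model

**Nodes and edge weights.** The node set is the 68-region Desikan-Killiany
parcellation (34 gyral regions per hemisphere), in a fixed canonical order
(odd atlas indices left hemisphere). For each group (e.g. a case group and a
control group), thickness at every ROI is first residualized by ordinary
least squares on an intercept, the subject's global mean thickness (mean over
the 68 ROIs), age, sex (1 = male, 0 = female) and the age x sex interaction.
Residualization is fitted per group by default because the networks are
per-group objects; a pooled fit is available (`within_group=False`) since the
convention differs across studies. Rank-deficient designs (e.g. a single-sex
group, where the interaction is collinear with age) drop the offending
columns left-to-right with a logged warning.

Note that the global-mean covariate is not a passive nuisance term: like
global signal regression in fMRI, it removes variance shared across regions
and therefore attenuates all positive inter-regional correlations (on
synthetic cohorts with planted within-module correlation 0.5, the
residualized within-module correlation is ~0.32). The relative within/between
module contrast survives, which is what module detection uses.
`residualize(..., include_global_mean=False)` disables the term.

The group network is the dense 68 x 68 matrix of pairwise Pearson
correlations of the residuals (K = 68·67/2 = 2278 edges; no thresholding or
binarization anywhere). The raw signed matrix is always retained. For
modularity-based metrics a weight policy is applied first —
`truncate_negative` (default), `absolute`, or `keep_signed` — and the policy
weights are then normalized by the total network weight L so that each
group's upper-triangle weights sum to 1, making module-connectivity sums
comparable across groups. Newman's Q is ill-behaved with negative strengths,
so `keep_signed` networks are flagged unsafe for the optimizer; the signed
matrix feeds only the edge-wise Fisher comparison, which is policy-free.

**Modularity and module metrics.** For a partition of the nodes into modules
s = 1..N_m,

    Q = Σ_s [ l_s / L − (d_s / 2L)² ]

with l_s the total edge weight inside module s, d_s the summed node strengths
of module s (strength = sum of incident edge weights) and L the total weight.
Module-level connectivity is MC_s = l_s and IMC_st = summed weight between
modules s and t, so Σ MC + Σ IMC = L exactly. Node roles under a partition:
the intra-module degree z-score MD_i standardizes a node's within-module
strength against the other nodes of its module (population SD; MD = 0 when
the module SD is 0 or the module is a singleton), and the participation
coefficient PC_i = 1 − Σ_s (κ_is / k_i)² with κ_is the node-to-module weight
and k_i the node strength (PC = 0 for isolated nodes, logged). Q, MD and PC
are invariant under global weight rescaling, hence unaffected by the L
normalization.

**Optimizer.** Partitions are found by a weighted Louvain scheme written for
this package: sweeps of greedy single-node moves, aggregation of modules into
super-nodes, repeated until converged, followed by a node-level refinement
sweep on the original graph; refinement and aggregation are cycled to a fixed
point. The search is restarted (default 100) from shuffled node orders, with
odd restarts starting from random coarse partitions rather than singletons —
greedy agglomeration otherwise funnels many node orders into the same basin.
Both the refinement cycle and the mixed initialization were required for the
optimizer to attain the enumerated global maximum on random 4–8-node
networks, which is how its correctness is anchored
(`exhaustive_best_partition` enumerates all set partitions, feasible to ~12
nodes). Everything is deterministic given the seed; modules of a returned
partition are labelled canonically (module 1 contains the lowest-index
node). Ties in move gains break toward the lowest module id; among equal-Q
restarts the first is kept.

**Baseline-partition strategy.** The full analysis optimizes the partition on
the control network only and imposes it on the case network; all Q / MC / IMC
/ MD / PC group comparisons are made under that single reference partition,
oriented case minus control everywhere.

## Inference

**Random-network null for Q.** Each replicate redistributes the multiset of
the 2278 upper-triangle weights uniformly over node pairs — N, K, the weight
multiset and hence L are preserved exactly — and re-scores Q on the fixed
partition (re-optimizing per replicate is available via `reoptimize=True`
but is ~100x slower and answers a slightly different question). Significance
is a one-sample t-test of the null sample against the observed Q; both
two-sided and one-sided p are reported since the direction of interest
(observed above null) is usually known.

**Subject-relabeling permutation test.** Group labels are permuted over the
pooled subjects with the original group sizes preserved; for every permuted
labelling the entire pipeline (residualize → correlate → policy → normalize →
metric under the fixed reference partition) is recomputed for both groups.
The pipeline evaluates a vector statistic — Q, all MC_s, all IMC_st, all
MD_i, all PC_i — in one pass per permutation, so one null sample serves every
measure. Two-tailed p-values use the add-one convention,
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), which is never exactly zero; the
plain u / n_perm proportion is available with `add_one=False`. Defaults are
10,000 permutations and 10,000 null networks; validation work in this
repository runs 1,000 (and 199 inside calibration loops), which bounds the
attainable p at ~1e-3 — adequate for directional claims at alpha = 0.05.

**Edge-wise Fisher comparison.** Per edge, z = atanh(r) and

    Z = (z_control − z_case) / sqrt(1/(n_case − 3) + 1/(n_control − 3)),

so a correlation *decreased* in the case group gives Z > 0. Two-tailed
normal p-values are corrected by Benjamini-Hochberg at q = 0.01 (step-up;
implemented via statsmodels) across all 2278 edges as one family. Edges with
|r| = 1 have infinite z; they are flagged and excluded from the FDR family
with a warning rather than silently dropped. The comparison is exactly
antisymmetric under a group swap.

## Synthetic cohorts

The generator emulates the study conditions the pipeline is meant for: two
groups of ~50 children aged 6–15 years (uniform ages, ~80% male), mean
thickness 2.5 mm with SD 0.5 mm, a negative linear thickness-age slope
(−0.02 mm/year), a small additive sex offset (0.1 mm), and a planted
3-module organization of the 68 ROIs with the 13/28/27 size profile typical
of a control-group solution. The stochastic part of thickness is drawn from
N(0, R) scaled to `noise_sd` mm, where R is a block-constant correlation
matrix: `r_within` (default 0.5) inside modules, `r_between` (default 0.1)
across them, plus per-group block perturbations (`group_effects`, applicable
to a module or a module pair). R is checked for positive semi-definiteness
by eigendecomposition (rejected otherwise with an explicit error) and
sampled through its eigen square root, so empirical correlations converge to
the planted targets as n grows (verified to ±0.02 at n = 2000). An optional
independent `measurement_sd` term adds unstructured noise (default 0, since
it attenuates the planted correlations). Values are clipped to the
physically displayed 0–5 mm range; the clipping rate is logged and is
essentially zero under defaults. Identical spec + seed reproduce a cohort
bit-for-bit.

The case/control fixture (`make_autism_like_pair`) lowers within-module
correlation by 0.3 in modules I and II and raises it by 0.3 in module III
for the case group, mirroring the direction of the module-connectivity
alterations the method is designed to detect, with matched covariate
distributions across groups.

What the generator does *not* emulate: spatial autocorrelation and
anatomical adjacency, hemispheric symmetry of correlations, scanner/site
effects, non-linear age trajectories, heavy-tailed or heteroskedastic
thickness noise, and any vertex-level structure. Passing tests therefore
demonstrate that the estimator and inference machinery recover known
block-covariance structure and are calibrated under exchangeability — not
that real cortical data satisfy those assumptions.

## Validation problem sizes

The repository's own checks run at desk scale, chosen to keep each property
sharply testable: optimizer-vs-enumeration on 100 random ≤8-node networks;
planted-partition recovery (N_m = 3, adjusted Rand index 1) on one control
cohort of n = 100; directional recovery of the fixture effects over 20 seeds
at n = 100/group with 1,000 permutations, requiring every sign and p < 0.05
in ≥19/20 seeds; permutation type-I error over 200 null simulations at
n = 50/group with 199 permutations each (accepted range 0.02–0.09 at nominal
0.05); and BH false-discovery proportion on 500 × 2278 uniform p-values
(mean indicator within two binomial standard errors of q = 0.01 — with all
nulls true the BH expectation equals q exactly, so a strict ≤ q check on a
finite mean would fail by construction half the time).

## Known limitations

- Louvain with restarts is exact on the small networks where enumeration is
  feasible and consistently recovers high-contrast planted structure at 68
  nodes, but carries no optimality guarantee on arbitrary 68-node networks.
- The negative-correlation policy is a genuine modelling fork: truncation,
  absolute value and signed retention answer different questions, and module
  metrics can differ materially between them. The default (truncate) follows
  the positive-covariance convention of thickness-network studies; the switch
  exposes the alternatives rather than hiding the choice.
- Group comparison assumes exchangeable subjects under the null; covariate
  imbalance between groups beyond what the residualization removes would
  violate that.
- The t-test against the random-network null treats the null sample as the
  comparison distribution; with re-scoring (default) the null is conditional
  on the reference partition.
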
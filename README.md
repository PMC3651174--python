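# covmod — modularity analysis of structural covariance brain networks

`covmod` is for researchers who study how the *modular organization* of the
cortex differs between groups — for example between children with autism and
typically developing controls — using structural covariance networks: graphs
whose 68 nodes are Desikan-Killiany cortical regions and whose edges are
across-subject Pearson correlations of regional mean cortical thickness.

From a plain subjects x ROIs thickness table the package

1. residualizes thickness at every ROI on global mean thickness, age, sex and
   age x sex (per group);
2. builds each group's dense weighted correlation network (K = 68·67/2 = 2278
   edges, no thresholding), applies a negative-weight policy and normalizes
   by total network weight L;
3. finds the control group's optimal modular partition by maximizing Newman's
   weighted modularity

       Q = Σ_s [ l_s / L − (d_s / 2L)² ]

   with a restarted Louvain optimizer (validated against exhaustive
   enumeration on small networks), and imposes that baseline partition on the
   case network;
4. compares groups on Q, intra-/inter-module connectivity (MC_s, IMC_st) and
   node roles (intra-module degree z-score MD_i, participation coefficient
   PC_i = 1 − Σ_s (κ_is/k_i)²) with subject-relabeling permutation tests, and
   checks Q against a random-network null that reshuffles the edge-weight
   multiset;
5. tests every edge with the two-sample Fisher statistic
   Z = (z_c − z_a)/√(1/(n_a−3) + 1/(n_b−3)), z = atanh(r), under
   Benjamini-Hochberg FDR at q = 0.01.

A planted-partition synthetic cohort generator (block-constant covariance
with verified positive semi-definiteness, linear age/sex effects, group-level
block perturbations) makes every stage testable without access to restricted
imaging data. See `docs/methods.md` for the full model and design choices.

## Worked example

Simulate a matched case/control cohort (60 subjects per group; the case group
has within-module correlation lowered by 0.3 in modules I and II and raised
by 0.3 in module III) and run the full analysis:

```bash
covmod simulate --out cohort.csv --seed 1 --n-subjects 60
covmod analyze --cohort cohort.csv --out results --seed 1 --n-perm 1000 --n-random 1000
covmod report --results results
```

prints

```
seed 1, groups {'autism': 60, 'control': 60}
control partition: 3 modules, Q = 0.5952
case Q under control partition = 0.3585
edges: 1 significant (0 decreased, 1 increased in case)
measure   case  control  diff_case_minus_control  perm_p
      Q 0.3585   0.5952                  -0.2368  0.0010
   MC_1 0.0549   0.1644                  -0.1095  0.0010
   MC_2 0.1471   0.3968                  -0.2497  0.0010
   MC_3 0.6831   0.4046                   0.2785  0.0010
IMC_1_2 0.1050   0.0141                   0.0909  0.0060
IMC_1_3 0.0015   0.0086                  -0.0071  0.3936
IMC_2_3 0.0084   0.0115                  -0.0031  0.7253
```

Reading this: the optimizer recovers the three planted modules in the control
network (Q = 0.595); imposing that baseline partition on the case network
drops modularity to 0.359 (permutation p = 0.001 at 1,000 permutations, the
smallest attainable value). Intra-module connectivity is significantly lower
in the case group for modules I and II and higher for module III — exactly
the planted perturbation, with all differences oriented case minus control.
`results/` also contains the per-node MD/PC table, the 2278-row Fisher edge
table with FDR flags, the control partition, and a JSON run log recording
every switch and seed so the run is reproducible bit-for-bit.

The same analysis runs on real data: `covmod analyze --cohort your.csv ...`
where the CSV has columns `subject_id, group, age, sex` followed by the 68
atlas abbreviations (`BSTS.L, BSTS.R, ..., INS.R`; see
`covmod.builtin_dk_atlas()`).

## Library use

```python
from covmod import (CohortSpec, make_autism_like_pair, residualize,
                    build_correlation_network, apply_weight_policy,
                    normalize_by_total_weight, optimize_partition)

case, control = make_autism_like_pair(CohortSpec(n_subjects=100, seed=0))
net = build_correlation_network(residualize(control)["control"])
net = normalize_by_total_weight(apply_weight_policy(net, "truncate_negative"))
result = optimize_partition(net, n_restarts=100, seed=0)
print(result.partition.n_modules, round(result.q, 3))   # 3 0.602
```

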
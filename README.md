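# phnet

Persistent-homology analysis of metabolic brain connectivity for small
clinical cohorts.

Regional ¹⁸F-FDG-PET uptake, correlated across subjects, defines a
*metabolic connectivity* network over the regions of a neurotransmitter
pathway (striatocortical and mesolimbic dopaminergic; Ch1–3, three Ch4
divisions and Ch5–6 cholinergic).  Instead of fixing one arbitrary edge
threshold, `phnet` sweeps a graph filtration over every threshold and
summarises how quickly the network assembles — a topological signature
that distinguishes diagnostic groups (healthy controls, subjective
cognitive decline, MCI, early Alzheimer's disease) even at n ≈ 20 per
group.

## The model

For one group and one pathway with ROI set *V*:

1. **Connectivity.** Pearson correlation *r(i,j)* of ROI uptake across
   subjects; dissimilarity *d(i,j) = 1 − |r(i,j)|*.
2. **Filtration.** For λ ∈ [0, 1], the graph G(λ) contains every pair
   with *d(i,j)* ≤ λ.  β₀(λ), the zeroth Betti number, counts connected
   components; it steps down from |V| to 1 exactly at the minimum
   spanning tree (MST) edge weights of *d*.
3. **Persistence summaries.** Barcode (one bar per ROI, death = merge
   threshold), single-linkage distance SLD(i,j) = minimax path distance
   (an ultrametric, rendered as a dendrogram / Newick tree), and the
   **SIP AUC** — the integral of β₀ over [0, 1], which satisfies
   SIP AUC = 1 + Σ(MST weights).  Larger = slower, less efficient
   network integration.
4. **Graph metrics.** On the edge-filtered weighted network:
   characteristic path length (CPL), network diameter (ND) and
   eigenvector centrality (EC, on similarity weights 1 − d).
5. **Inference.** Group contrasts by subject-label permutation tests
   (group sizes preserved, the statistic recomputed from the correlation
   step onward per shuffle; two-sided, add-one smoothed p).

Because the underlying patient data are not public, the package ships a
synthetic cohort generator: block-exchangeable multivariate-normal
groups whose within-pathway correlation strength encodes disease
severity (HC 0.70 > SCD 0.60 > AD 0.45 > MCI 0.35, plus measurement
noise).  Every pipeline stage is developed and tested against it.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # 4 groups x 69 ROIs
python analysis/02_persistence_analysis.py   # filtration of every network
python analysis/03_group_comparison.py       # permutation contrasts
python analysis/04_severity_ordering.py      # ordering reproducibility
```

`02_persistence_analysis.py` prints the SIP AUC per pathway and group
(seed 7):

```
group                      MCI     AD    SCD     HC
ch1_3                    5.303  3.540  3.311  3.074
ch4_lateral_capsular     5.194  4.701  4.645  3.530
...
MEAN                     5.516  4.174  4.536  3.684
```

Reading: in this cohort the MCI-like group needs the largest filtration
budget to assemble its networks (highest aggregation cost, i.e. weakest
metabolic coupling), the HC-like group the smallest.  The cohort-level
permutation contrasts from `03_group_comparison.py`:

```
group_a group_b  sip_auc_a  sip_auc_b  difference  p_value
     AD     MCI      4.174      5.516      -1.342   0.0060
    MCI      HC      5.516      3.684       1.832   0.0020
    SCD      HC      4.536      3.684       0.852   0.0859
```

and `04_severity_ordering.py` reports how often the strict per-cohort
ordering MCI > AD > SCD > HC of the aggregation cost recurs across 100
replicate cohorts (63%, with the SCD-vs-HC pair the limiting contrast —
see `docs/methods.md`).

The same workflow is available as a CLI (`phnet simulate`,
`phnet analyze`, `phnet compare`, `phnet snapshots`), driven by a saved
YAML config; a checksum manifest makes runs verifiably reproducible.

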
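# wfclust

Weighted clustering and hierarchical classification of scientific
(bioinformatics) workflow collections.

Curated workflow repositories — pipelines built in workflow management
systems such as Galaxy or Taverna — accumulate hundreds of
related analyses. Grouping them supports batching similar workflows on a
server, dispatching long ones, and keyword search over a repository.
`wfclust` implements a complete toolchain for this problem, aimed at
researchers studying workflow similarity and at repository maintainers:

1. **Encodings.** A collection of workflow DAGs becomes a variables ×
   workflows matrix **W** with a non-negative per-variable weight vector
   **y**: Type I (task presence/absence, execution-time weights), Type II
   (task occurrence counts, keyword weights), Type III (pair-of-tasks
   counts plus terminal-task singletons, summed-time weights), Type IV
   (pairs plus `INPUT_*`/`OUTPUT_*` port counts, keyword weights).
2. **Weighted distances.** Euclidean
   `d_ij = sqrt(Σ_p y_p (w_ip − w_jp)²)` and cosine
   `d_ij = 1 − Σ_p y_p w_ip w_jp / (‖w_i‖_y ‖w_j‖_y)`.
3. **Partitioning.** Weighted k-means and k-medoids minimizing
   `Σ_k [Σ_{i,j∈k} d_ij²]/n_k` over multi-start protocols, with the
   Calinski–Harabasz, Silhouette and logSS indices to select the number of
   clusters K.
4. **Stability.** Pairwise support PS(w_i, w_j) (co-clustering frequency
   over Q randomized runs; diagonal = singleton frequency) and the global /
   per-element PSG scores aggregating `max(PS, 1 − PS)`, ranging 0.5
   (maximal instability) to 1 (full stability).
5. **Hierarchical classification.** UPGMA and neighbor joining on any
   workflow distance matrix, multifurcating reference trees from class
   labels, Robinson–Foulds comparison, a weighted least-squares fit score,
   Newick and PHYLIP I/O.
6. **Evaluation & simulation.** Plain Rand index against reference labels
   and a synthetic generator for labelled, class-structured workflow
   collections with a tunable class-mixing probability ε.

See `docs/methods.md` for the formulas, conventions and design decisions.

## Worked example

The package ships a five-workflow phylogenetic-analysis collection
(`figure1_fixture`) whose encodings are fully known. Selecting K with
weighted k-means (Euclidean distance, CH index, 1000 random starts per K):

```python
import wfclust as wf

ws = wf.figure1_fixture()
enc = wf.encode(ws, "I")                      # presence/absence encoding
sel = wf.select_k(enc, "kmeans", "euclidean", "CH",
                  k_min=2, k_max=4, n_starts=1000, seed=1)
print(sel.to_frame().to_string(index=False))
print(sel.chosen_k, sel.chosen_partition.clusters())
```

```
 K  index_value  objective     ss_b     ss_w  chosen
 2     2.146692   7.153333 2.559333 3.576667   False
 3     2.057807   4.013333 4.129333 2.006667   False
 4     2.449433   1.470000 5.401000 0.735000    True
4 [['W4'], ['W5'], ['W1'], ['W2', 'W3']]
```

CH peaks at K = 4: the two pipelines sharing the ClustalW2/PhyML/HGT core
(W2, W3) are grouped and the remaining workflows are singletons. With
best-of-1000 starts on n = 5 this is the global optimum of the dispersion
objective (the tests confirm it by enumerating all partitions).

How robust is that grouping? Run the stability protocol — 1000 randomized
runs, each re-selecting K from a single random start per candidate, under
the cosine distance:

```python
res = wf.stability_run(enc, "kmeans", "cosine", "CH",
                       k_min=2, k_max=4, Q=1000, seed=1)
print(res.ps_frame().round(2))
print(round(res.psg, 3), [round(v, 3) for v in res.psg_per_element])
```

```
      W1    W2    W3    W4    W5
W1  0.67  0.16  0.16  0.01  0.15
W2  0.16  0.25  0.41  0.02  0.36
W3  0.16  0.41  0.30  0.01  0.31
W4  0.01  0.02  0.01  0.96  0.01
W5  0.15  0.36  0.31  0.01  0.35
0.822 [0.84, 0.76, 0.762, 0.984, 0.764]
```

W4 — the only workflow sharing no tasks with the others — is a singleton in
96% of runs and is the most stable element (PSG(W4) = 0.98). W2, W3 and W5
sit at three nearly tied cosine distances, so randomized runs split over
their pairings (supports near 1/3–0.4) and drag the global PSG down to
0.82: exactly the low-support elements the PS/PSG scores are designed to
expose.

Hierarchical classification of the same matrix and comparison against the
known grouping:

```python
D = wf.distance_matrix(enc, "cosine")
tree = wf.upgma(D)
ref = wf.reference_tree({"W1": "pipeline", "W2": "pipeline",
                         "W3": "pipeline", "W5": "pipeline",
                         "W4": "comparison"})
print(wf.write_newick(tree))
print(wf.rf_distance(tree, ref))
```

```
(W4:0.46905959130379904,(W1:0.3042682799549391,(W5:0.1620896495371929,(W2:0.1330454568586432,W3:0.1330454568586432):0.029044192678549713):0.1421786304177462):0.16479131134885994);
2
```

The same operations are available from the shell:

```sh
wfclust encode --type 2 --keyword HGT workflows.json matrix.csv
wfclust cluster --encoding 1 --metric euclidean --starts 1000 --seed 1 workflows.json
wfclust stability --encoding 1 --metric cosine --runs 1000 --seed 1 workflows.json
wfclust distances --encoding 1 --metric cosine workflows.json dist.csv
wfclust tree --method nj dist.csv tree.nwk
wfclust rf tree.nwk other.nwk
wfclust rand labels_a.csv labels_b.csv
wfclust simulate --config sim.json collection.json
```

## Workflow JSON schema

```json
{
  "task_pool": [
    {"id": "PhyML", "name": "PhyML", "category": "tree-inference",
     "avg_exec_time": 1.13, "annotations": ["maximum likelihood"]}
  ],
  "workflows": [
    {"id": "W2", "instances": ["Seq-Gen", "ClustalW2", "PhyML"],
     "edges": [[0, 1], [1, 2]],
     "inputs": ["Tree"], "outputs": ["Matrix", "Results"],
     "class_label": "pipeline"}
  ]
}
```

Reference labels are two-column CSVs `workflow_id,class_label` with a
header.

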
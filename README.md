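# cphyt

Distance-preserving graph-neural-network embeddings of tumor phylogenetic
trees, with a synthetic benchmark, ensemble progression scoring, and
survival-analysis applications.

A phylogenetic tree here is a rooted directed tree whose nodes carry *sets*
of somatic alterations (the root is the germline, labeled by the empty
set).  The infinite-sites assumption is relaxed: alterations may repeat
across nodes, labels may be empty, and unseen alterations are handled at
embedding time.  A two-layer graph-convolutional network maps each tree to
a fixed-length vector; training is unsupervised and matches pairwise
Euclidean embedding distances to an extended ancestor-descendant (AD) tree
distance.  The network is implemented directly in NumPy/SciPy (forward and
backward passes, batch-norm, dropout, Adam), so no deep-learning framework
is required.

## Layout

| module | contents |
| --- | --- |
| `cphyt.trees` | data model, validation, JSON / edge-list TSV I/O, vocabulary, edge-count filtering, gene-level collapsing |
| `cphyt.distance` | extended AD distance (ancestor + co-cluster alteration pairs), pairwise distance matrices |
| `cphyt.encoding` | alteration-based (lambda) and clone-based node encodings |
| `cphyt.model` | the GNN, distance-matching training loop, embedding of unseen trees, supervised survival head, checkpoints |
| `cphyt.simulate` | seeded generators for five clustered-benchmark scenarios |
| `cphyt.clustering` | k-means, Rand Index, hierarchical tree clustering, matched random baseline, outlier filter |
| `cphyt.ensemble` | per-cluster progression scorers with max-score ensembling; edge-frequency reference scorer |
| `cphyt.survival` | baseline tree encodings, Kaplan-Meier, log-rank, concordance indices, survival-SVM wiring |

## CLI

```sh
cphyt simulate --scenario III --clusters 3 --per-cluster 50 --seed 7 --out sim/
cphyt validate sim/trees.json
cphyt distmat sim/trees.json --normalized --out matrix.tsv
cphyt train --trees sim/trees.json --out model/ --epochs 200 --seed 0
cphyt embed --model model/ --trees sim/trees.json --out emb.tsv
cphyt cluster --embeddings emb.tsv --k 3 --seed 0 --out clusters.tsv
cphyt rand-index clusters.tsv sim/truth.tsv
cphyt ensemble fit --trees train.json --embeddings emb.tsv --k 3 --out ens.pkl
cphyt ensemble score --model ens.pkl --trees test.json --out scores.tsv
cphyt survival clusters --embeddings emb.tsv --survival surv.tsv --k 2 --out survout/
cphyt survival predict --model model/ --trees trees.json --survival surv.tsv
```

Tree datasets are JSON arrays of objects
`{"patient_id": ..., "root": ..., "nodes": [{"id", "label"}], "edges": [[p, c]]}`;
single trees can also be given as three-column TSV edge lists
(`parent, child, child_labels` with semicolon-separated labels).
Survival tables are TSV with columns `patient_id`, `time`, `event`.

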
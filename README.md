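# hc4n

Hierarchical overlapping clustering of IP/MS bait-prey data for discovering
protein complexes at multiple interaction levels.

## The problem

Immunoprecipitation followed by mass spectrometry (IP/MS) pulls down a bait
protein together with its binding partners.  Across many IPs this yields a
protein-by-experiment matrix of occurrences (0/1) or abundances in which
protein interaction shows up as co-occurrence — but at very different
strengths depending on the *interaction level*: members of a stable complex
**core** co-occur almost always, a **complex** (core plus attachments) less
so, and an **assembly** of transiently interacting complexes only weakly.
Flat clustering at a single similarity level cannot tell these apart.

`hc4n` is for proteomics researchers who want to explore an IP/MS screen
across these levels at once.  It implements:

- **4N** ("near neighbor networks"): overlapping clustering at one
  strictness level.  A network is a protein set whose pairwise
  **co-occurrence** `C(i,j) = |IPs with both| / |IPs with either|` (a
  Jaccard index) meets a threshold `t_co`, whose **set-wise completeness**
  (fraction of within-set pairs meeting `t_co`) meets `t_comp`, and — for
  abundance data — whose profiles pairwise subtend an angle of at most
  `t_ab` degrees (default 40).  Networks overlapping by more than a given
  coefficient (default 50%) are joined.
- **HC4N**: the hierarchical strategy.  4N is run on the full matrix
  (manual or automatic level-1 strictness); each resulting cluster is
  extracted as a sub-matrix (the cluster's proteins plus every IP where any
  of them occurs) and re-clustered with automatically tightened thresholds,
  recursively.  The result is a tree whose root holds all proteins and
  whose node depth tracks interaction level: each node is annotated with
  the minimum pairwise co-occurrence of its members, non-decreasing from
  root to leaf.
- **Automatic thresholds**: the strictest `(t_co, t_comp)` grid setting at
  which every protein still lands in at least one cluster.
- **HC-plot**: a protein-by-protein heatmap in co-occurrence units; nested
  brighter squares are tighter sub-clusters, black cells mark pairs never
  clustered together.
- **Evaluation** against a reference complex catalog with the standard
  complex-prediction scores: sensitivity `Sn = Σᵢ maxⱼ Tᵢⱼ / Σᵢ Nᵢ`,
  positive predictive value `PPV = Σⱼ maxᵢ Tᵢⱼ / Σⱼ Σᵢ Tᵢⱼ`, accuracy
  `= √(Sn·PPV)`, and the separation score that penalizes splitting one
  complex across many clusters (`Tᵢⱼ` = size of the intersection of complex
  *i* and cluster *j*).
- **A synthetic-data generator** that plants cores, complexes, assemblies,
  shared proteins and background contaminants with known ground truth, for
  testing and method exploration.

## Worked example

Simulate a screen (8 planted cores, 4 complexes, 2 assemblies, 2 shared
proteins, 6 contaminants, 200 IPs), analyse it, and score the result:

```sh
hc4n simulate --out-dir demo --seed 7 --n-ips 200
hc4n run --input demo/matrix.tsv --out-dir demo/run --t-co 0.2 --t-comp 1.0
hc4n plot --tree demo/run/tree.json --out demo/hcplot.png
hc4n eval --tree demo/run/tree.json --catalog demo/truth_cores.tsv
```

The run prints the thresholds chosen at every node and ends with

```
tree with 16 nodes -> demo/run/tree.json
```

The tree (also exportable with `hc4n export` as GraphML/SIF for Cytoscape)
looks like this — `min_co` is each node's minimum pairwise co-occurrence:

```
 n0  level=0 min_co=0.00 n=39
   n1  level=1 min_co=0.18 n=10
     n5  level=2 min_co=0.22 n=9
     ...
   n4  level=1 min_co=0.32 n=8
     n11 level=2 min_co=0.44 n=7
       n13 level=3 min_co=0.98 n=3
       n14 level=3 min_co=1.00 n=3
```

Level-1 nodes at `min_co` 0.15–0.32 are the planted complexes; the
`min_co ≈ 1.0` triples at level 3 are recovered stable cores.  Scoring the
flattened tree against the planted core catalog prints

```
reference complexes : 8
predicted clusters  : 4
sensitivity         : 1.0000
PPV                 : 0.5000
accuracy            : 0.7071
separation          : 0.7071
```

— every core protein is covered (sensitivity 1), but the flat, joined
clusters are whole complexes, each spanning two cores, hence PPV 0.5: the
flat view loses exactly the distinction the tree keeps.

The intended workflow is exploratory: run with `--t-co auto --t-comp auto`,
inspect the HC-plot, adjust the level-1 strictness, and re-run.  Nodes with
low co-occurrence but several tighter children (listed in `sois.tsv`) are
*subsets of interest* — stacks of interacting complexes worth re-analysing
as a standalone dataset with `hc4n soi --node-id <id> --t-co <lower> ...`,
which is how shared proteins are surfaced in several clusters at once.

## Layout

| Module | Contents |
| --- | --- |
| `hc4n.data_io` | matrix/catalog/cluster readers and writers, subset extraction |
| `hc4n.similarity` | co-occurrence, completeness, abundance angle, thresholds |
| `hc4n.fourn` | 4N: network growth, joining, automatic thresholds |
| `hc4n.tree` | HC4N recursion, SOI flagging, flattening, tree JSON |
| `hc4n.evaluation` | sensitivity / PPV / accuracy / separation |
| `hc4n.visualization` | HC-plot rendering, GraphML/SIF export |
| `hc4n.simulate` | synthetic bait-prey generator with ground truth |
| `hc4n.cli` | `hc4n simulate / run / soi / plot / export / eval` |

See `docs/methods.md` for the model, its assumptions and design choices.
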
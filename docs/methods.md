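# Methods

## Similarity measures

The unit of information is the protein-by-IP matrix; a protein *occurs* in
an IP when its value there is strictly positive.  Three measures define
clustering strictness:

- **Co-occurrence** `C(i,j)`: the Jaccard index of the two proteins'
  occupied-IP sets — IPs where both occur over IPs where either occurs.
  It is 1 exactly for identical occupancy, 0 for disjoint occupancy, and
  it is invariant under subset extraction (below), which is what makes the
  hierarchical recursion coherent.
- **Set-wise completeness** of a protein set at level `t_co`: the fraction
  of unordered within-set pairs with `C ≥ t_co`.  Completeness 1 means the
  set is a clique at level `t_co`; lower thresholds admit looser,
  overlapping networks.  (Pairs at exactly the threshold count as passing;
  comparisons carry a 1e-9 slack so ratios of small integers are not lost
  to float rounding.)
- **Abundance angle** (abundance data only): the angle in degrees between
  two proteins' abundance profile vectors, i.e. arccos of their cosine
  similarity.  The threshold `t_ab` is a maximum angle; the default 40°
  corresponds to cosine ≥ cos 40° ≈ 0.766.  A threshold in degrees is used
  because the criterion is a cosine similarity and a bare "40" can only be
  an angle.  For 0/1 data the criterion is vacuously true.

Occurrence information and abundance information are kept separate by
design: abundance magnitudes affect only the angle criterion, never
co-occurrence.

## 4N: near neighbor networks

One network is grown per seed protein, greedily and deterministically:

1. Candidates are the proteins whose co-occurrence with the seed meets
   `t_co` (and, for abundance data, whose angle to the seed is within
   `t_ab`).
2. Repeatedly, the candidate with the highest mean co-occurrence to the
   current members (ties broken lexicographically by identifier) is added,
   provided it passes the abundance criterion against every member and the
   enlarged set keeps completeness ≥ `t_comp`.
3. Growth stops when no candidate can be added; a seed that attracts
   nobody yields no network.

Networks with identical member sets are deduplicated, then networks whose
overlap coefficient `|A∩B| / min(|A|,|B|)` strictly exceeds the join
threshold (default 0.5) are merged to a fixed point.  The min-size
denominator means a set fully contained in another always merges into it —
the intended behaviour for near-duplicate networks.  Every cluster is
annotated with its minimum pairwise co-occurrence, the value by which its
interaction level is judged.

The greedy constructive order is a design choice (the defining conditions
— pairwise co-occurrence, completeness, abundance similarity — do not fix
a construction); it is compared against a brute-force enumeration of
maximal feasible seed-containing sets in the test suite and agrees on ≥95%
of random instances, the remainder being classic greedy-vs-optimal cases.

## Automatic thresholds

Unset thresholds are resolved to the strictest setting, on a descending
grid of step 0.01 (two decimals, matching the precision such thresholds
are usefully reported at), at which **no protein is lost** — every protein
belongs to at least one cluster of size ≥ 2.  With both thresholds free
the pair is maximized lexicographically, `t_co` first, since co-occurrence
is the primary strictness axis (it is the unit of the HC-plot and of node
annotation).  The search is capped above by the smallest best-partner
co-occurrence over proteins: a protein whose best partner sits below
`t_co` can never enter any network.

A property of the greedy growth rule worth knowing: on occurrence data a
protein with any partner at `t_co` always forms at least a pair, and a
pair has completeness 1, so the automatic completeness value is always 1.0
whenever `t_co` is feasible — the completeness knob only bites when set
manually (or through the abundance criterion).  Implementations that build
a network as the seed's *entire* neighborhood and discard incomplete
neighborhoods behave differently there; with greedy growth, strict
automatic completeness simply means networks are grown as cliques.

## HC4N: the hierarchy

Level 1 is a 4N run on the full matrix with manual or automatic
strictness.  For each cluster of ≥ `min_split_size` (default 3, the
smallest set that can split into two clusters of ≥ 2) proteins, the
sub-matrix of its proteins *plus every IP where any of them occurs* is
extracted and 4N re-run with automatic thresholds.  Because extraction
keeps all occupied IPs of every member, both the intersection and union
counts of member pairs are preserved, so pairwise co-occurrence inside a
subset equals its full-data value (asserted on every recursion step), and
node `min_co` is non-decreasing along every root-to-leaf path.

A node becomes a leaf when 4N returns only the node's own member set, when
it is too small to split, at `max_depth` (default 10, a safety valve —
observed trees are shallow), or when no threshold setting keeps all its
proteins (demoted with a warning rather than aborting the run).  A child
with the same member set as its parent is never added, so every path
strictly shrinks and termination is guaranteed.

Non-root nodes with low `min_co` and at least two children are flagged as
**subsets of interest (SOIs)**: stacks of overlapping or interacting
complexes.  Flagging is advisory only; the follow-up — re-analysing the
node's proteins as a standalone dataset with manually lowered strictness —
is a user-driven second invocation (`hc4n soi`), not a recursion change.

For tree-free comparison and evaluation the tree is *flattened*: all
non-root clusters, deduplicated, joined at overlap > 0.6.  Since every
child is contained in its parent (overlap coefficient 1), flattening
effectively reports the coarsest distinct clusters; the tree is where the
fine structure lives.

## Evaluation scores

Standard complex-prediction scores over the contingency table
`T[i,j] = |complex_i ∩ cluster_j|` with complex sizes `N_i`:

- sensitivity `Σᵢ maxⱼ T[i,j] / Σᵢ Nᵢ` (size-weighted best-match recall);
- PPV `Σⱼ maxᵢ T[i,j] / Σⱼ Σᵢ T[i,j]` (marginal-weighted best-match
  purity) — clusters containing no catalogued protein have zero column
  marginal and drop out of both numerator and denominator;
- accuracy `√(Sn × PPV)`;
- separation: with `F[i,j] = (T[i,j]/rowᵢ)(T[i,j]/colⱼ)`, the geometric
  mean of the complex-wise mean of row sums of `F` and the cluster-wise
  mean of its column sums; 1 exactly for a disjoint one-to-one prediction.
  Unweighted arithmetic means are used for the two averages (the cited
  scheme's default).

Because only the best-matching cluster counts for each complex, producing
many extra clusters does not lower sensitivity, and unannotated clusters
do not lower PPV; separation is the score that penalizes over-splitting.
Accuracy rounds to two decimals reproduce the published per-run values for
four of five published (Sn, PPV, accuracy) triples; the remaining one
(0.88, 0.58 → 0.714) rounds to 0.71 against a printed 0.72, i.e. the
printed inputs there are themselves rounded.

## Synthetic data generator

`plant_hierarchy` lays out disjoint cores (3 proteins each by default),
assigns cores round-robin to complexes and complexes to assemblies, adds
per-complex attachment proteins, proteins shared between seeded-random
complex pairs (several may share a pair), and a background contaminant
pool.  Ground truth is returned as a catalog per level (cores, complexes,
assemblies).

`simulate_ips` draws one bait per IP — round-robin over planted proteins,
then seeded-random, so every planted protein is a bait at least once when
the IP count reaches the planted protein count — and detects every other
protein at the probability of its tightest relationship to the bait:
same core `p_core` (0.95) > same complex `p_attach` (0.6) > same assembly
`p_assembly` (0.2) > background `p_background` (0.01).  **Cores are
captured all-or-none**: the draw is made once per core per IP, and on
success the whole core appears.  Unit capture is the defining property of
a stable core — its members occur together throughout the data — and it
is what cleanly places within-core pairs at the top of the co-occurrence
ordering; with independent per-protein draws, same-core and
same-complex pairs end up within a few hundredths of each other and no
co-occurrence method (at any threshold) can recover the planted cores.
Marginal detection probabilities are unaffected by this choice.
Attachments, shared proteins and contaminants are independent Bernoulli
draws given the bait.  For abundance data, detected values are log-normal
(μ=2, σ=0.5 on the log scale) scaled by a per-tier factor.

The default configuration (8 cores × 3 proteins, 4 complexes × 2
attachments, 2 assemblies, 2 shared proteins, 6 contaminants, 200 IPs, 40
proteins in total) is a desk-scale miniature of the published screens'
structure.  What the generator does *not* emulate: peptide-level
detectability, abundance-dependent missingness, correlated contamination.
Passing tests on it therefore demonstrate that the algorithm recovers
tiered co-occurrence structure, not that it is robust to every noise
process of real spectrometry data.

## Behaviour worth knowing (and known limitations)

- **Where the assembly level appears.**  With background noise present
  (default generator settings), the automatic level-1 thresholds are
  dragged down by the weakest contaminants and level 1 captures whole
  assemblies.  In noise-free data every protein retains a strong partner
  inside its complex, the automatic `t_co` lands at the complex tier
  (~0.4), and assemblies never appear as tree nodes; they are reachable
  only by manually lowering level-1 strictness to the cross-complex
  co-occurrence tier (~0.15) — the same move as the SOI workflow.
- **When complexes fail to split into cores.**  Inside a complex subset
  the automatic `t_co` is capped by the attachments' best links.  When the
  attachment-to-core co-occurrence sits at that cap (which happens
  systematically for `p_attach ≈ 0.7`), the attachment's network overlaps
  the core clique by more than the 50% join threshold, the whole subset is
  glued back into a single trivial cluster, and the node becomes a leaf
  before its cores separate.  Core recovery against the planted catalog
  then plateaus around accuracy 0.85–0.9 instead of 1.0.  Lower `p_attach`
  (looser attachments), fewer attachments, or a manual stricter re-run on
  the flagged node all split such complexes cleanly.
- Determinism: 4N, HC4N and the evaluation contain no randomness; the
  generator is fully determined by its seed.  Re-runs with identical
  inputs produce byte-identical tree JSON.
- Degenerate inputs: empty matrix rows/columns are dropped with a warning
  on load; NaN and negative values are hard errors (silent imputation
  would corrupt co-occurrence); an all-zero contingency table scores 0
  with a warning rather than erroring.
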
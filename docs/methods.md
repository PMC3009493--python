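# Methods

## Overview

`sfssclass` implements a three-stage multiclass tumor classifier for miRNA
expression profiles: (1) SAMBA-style biclustering of the standardized
training matrix, (2) selection of biologically supported biclusters —and of
their miRNAs and samples — against a cancer–miRNA association network, and
(3) an uncorrelated shrunken centroid (USC) classifier whose shrinkage Δ and
correlation threshold ρ are chosen by ten random fourfold cross-validations.
This note records the model assumptions, the numerical conventions, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Preprocessing

Raw intensities are floored at `floor` (default 1) and log2-transformed;
low-expression miRNAs are removed by one rule with two conventional
settings: keep a miRNA iff its log2 value reaches `cutoff` in at least
`min_count` samples. `min_count=1` with cutoff 7.25 discards miRNAs that
never reach the cutoff anywhere; `min_count=ceil(0.10·n)` with cutoff 8
requires expression in at least 10% of samples ("at least" rounds up, so
n=43 gives 5). The comparison is inclusive (a value exactly at the cutoff
counts). Standardization brings each miRNA to mean 0 / sd 1 using the
sample (n−1) standard deviation — the common expression-analysis
convention. Standardization statistics are always fit on training data only
and applied unchanged to held-out samples; any other choice leaks test
information. A miRNA constant within a CV training split carries no class
signal; its sd is replaced by 1 (pure centering) rather than aborting the
split.

## Biclustering

The standardized matrix is discretized at ±t standard deviations (default
t = 1) into up/unchanged/down responses. The bipartite feature–sample graph
whose edges are the nonzero responses gets log likelihood-ratio weights
under a uniform-density null: a present pair scores log(p_c/p̂), an absent
pair log((1−p_c)/(1−p̂)), where p̂ is the observed response density and
p_c (default 0.9, required > p̂) the assumed within-bicluster response
probability. A bicluster's score is its submatrix's summed weight, so
maximizing score is a heavy-subgraph search. This is a deliberately
simplified form of the SAMBA family of models: the null is uniform rather
than degree-corrected, and up/down responses are by default both plain
"responses". A `coherent_signs` flag searches the up- and down-response
graphs separately (weights against the per-sign density) for settings where
the expected signal is sign-coherent; this halves the effective noise
density and is what the planted-block analyses use.

Search: for every sample vertex with degree ≤ d (default 30), all feature
subsets of its neighborhood of size 2..k (default 3) are scored as seeds —
a seed's sample set is every sample responding on all its features — and
the n_keep (default 20) best per vertex are kept. On graphs with ≤ 15
features all subsets are seeded outright. Each seed is refined by local
search: because the score is a sum of independent pair weights, the optimal
sample set given the features (and vice versa) is closed-form — keep every
element with positive total contribution, topped up to the 2-element
minimum — and these exact one-axis re-optimizations alternate with greedy
single add/remove moves until neither improves. Single-move-only hill
climbing was measurably weaker: it gets stuck in local optima on instances
small enough to enumerate exhaustively, and it cannot start at all when no
feature pair shares two responding samples. Results are emitted in score
order subject to a pairwise Jaccard bound (default 0.25) on the union of
feature and sample sets. All tie-breaks are by lexicographic vertex ID, so
the procedure is fully deterministic. Biclusters never shrink below
2 features × 2 samples, which keeps the search space aligned with the
exhaustive-enumeration oracle used in testing.

Parameter guidance: the degree cap d exists to bound seed enumeration. At
t = 1 the background response rate of standardized noise is
2(1−Φ(1)) ≈ 0.317, so with p features every sample vertex has expected
degree ≈ 0.317·p; d must sit above that or no vertex is seeded. The
pipeline's synthetic-study configuration therefore sets d = p (=100). Cost
grows as vertices × C(d, k), which stays comfortable at these sizes.

## Network-guided selection

A bicluster is *potential* if at least one of its miRNAs is associated in
the network with the cancer type of at least one of its samples. From a
potential bicluster, all miRNAs are kept (bicluster members are likely
co-regulated), and a sample is kept iff its cancer type is adjacent to at
least one miRNA *of that bicluster* — the bicluster-specific reading; the
looser "class appears anywhere in the network" variant is available via
`class_anywhere`. Under the strict reading, tumor types whose dysregulated
miRNAs never co-cluster lose all their samples; such classes are dropped
from training and listed in the selection report. Edge directions (up /
down / mixed / unknown) are stored but ignored for relevance, since the
rule is about association, not direction. Identifiers match
case-insensitively after trimming because literature-derived names vary.

## The USC classifier

Formulas as in the README. Numerical conventions:

- m_k = √(1/n_k − 1/n), the standard-error factor of a class-vs-overall
  centroid contrast; `mk_mode="plus"` switches to √(1/n_k + 1/n) for
  comparison studies.
- s_0 is the median of the s_i — a robustness offset against near-zero
  within-class dispersions.
- Decorrelation ranks features by pre-shrinkage max_k |d_ik| (shrunken
  values tie at zero too easily), scans in decreasing rank with
  lexicographic ID tie-break, and compares absolute Pearson correlation
  across training samples against ρ with an inclusive bound, so ρ = 1
  provably keeps everything and USC reduces to SC.
- Priors default to empirical n_k/n; uniform is available.
- Prediction ties (exactly equal discriminant scores) go to the
  lexicographically first class label and are flagged.
- Fitting requires K ≥ 2 classes with n_k ≥ 2 each (the pooled variance
  needs within-class replication); a Δ that empties the feature set raises
  a dedicated error, which cross-validation records as a failed grid cell
  with error 1.0.

## Cross-validation

Ten repeats of stratified fourfold CV (defaults; both configurable). Folds
are dealt per class round-robin from a seeded shuffle, so per-class fold
sizes differ by at most one; a singleton class is pinned to the training
side of every split with a warning. Repeat r uses seed + r. Within each
split, standardization and all centroid statistics are recomputed on the
training folds only. The per-split grid evaluation shares centroid
statistics and the feature correlation matrix across all (Δ, ρ) cells; a
test guarantees this optimized path is numerically identical to fitting
each cell from scratch. The selected (Δ*, ρ*) minimizes mean error over
repeats × folds; ties prefer larger Δ, then smaller ρ (the most
parsimonious model). Biclustering and network selection run once on the
full training set before CV, matching the pipeline's linear flow; a
leakage-free benchmark can instead re-run selection inside each split by
driving the library calls directly.

## Synthetic data

`make_classification_data` draws i.i.d. N(0,1) background and shifts each
class's p_info informative miRNAs by +effect in that class's samples —
i.e. additive mean shifts on an (implicitly log-scale) standardized
background, with disjoint informative sets per class.
`make_planted_bicluster_data` plants shifted rectangular blocks along the
diagonal of a noise matrix. `make_network` turns the true (class,
informative-miRNA) pairs into edges with probability `coverage` and adds
false edges at `false_edge_rate`. All generators are bit-reproducible given
their seed.

What this emulates: class-specific over-expression signatures, co-expressed
blocks, and a literature network that covers the signature with adjustable
completeness and noise. What it does not: heavy-tailed measurement error,
array batch effects, correlated background structure between miRNAs,
class-imbalanced cohorts, or the partial and biased coverage of a real
literature-mined network. Passing tests therefore demonstrate correctness
of the algorithms and recoverability under idealized Gaussian conditions,
not expected accuracy on clinical data.

Study conditions used by the end-to-end analyses and `scripts/acceptance.py`:
K = 5 classes, p = 100 miRNAs, n_k = 20 training and 20 held-out samples
per class, 5 informative miRNAs per class, effect 3 sd, full network
coverage with no false edges; biclustering at t = 1, p_c = 0.9, d = p;
CV over Δ ∈ {0, 0.1, …, 2.0} × ρ ∈ {0.5, …, 1.0}, 10 repeats × 4 folds.
These sizes keep a complete run around two seconds on one CPU while leaving
the recovery problem non-trivial (48 of 126 grid cells are typically
non-zero-error).

The planted-bicluster recovery analysis uses a 6×5 block shifted by +3 over
unit noise in a 30 × 60 matrix, searched sign-coherently at t = 1.2. The
sizing follows a detectability analysis: standardization of a block-bearing
miRNA inflates its sd by √(1 + shift²·f(1−f)) for block sample fraction f,
so at n = 30 (f = 1/6) the discretized block retains too few of its 30
pairs to dominate the densest noise clique reliably, while at n = 60
(f = 1/12) with the per-sign null the block is recovered with Jaccard
≥ 0.9 across a ten-seed sensitivity scan.

## Known limitations

- The biclustering null is uniform-density; hub miRNAs or outlier samples
  would be better handled by a degree-corrected null.
- The seed stage enumerates subsets only up to k (vectorized for k ≤ 3;
  generic enumeration beyond), so very wide biclusters must be reached by
  local growth.
- Greedy decorrelation is order-dependent by design (rank order); it does
  not find a maximum-weight uncorrelated subset.
- Cross-validation error is plain misclassification rate; with strongly
  imbalanced classes a balanced measure would be preferable.
- GCT support is the v1.2 dialect only; missing values are rejected unless
  row-mean imputation is explicitly requested.
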
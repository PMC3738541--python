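# Methods notes

## Model and assumptions

The predictor is a guilt-by-association ranker on a bipartite
miRNA–disease label store. Its single modeling assumption is that
functional similarity of miRNAs — measured entirely through the semantic
similarity of their associated disease groups — is informative about
unobserved associations, and that this signal is locally concentrated:
only the *k* most similar neighbors of a candidate are consulted, and
only their labeled members contribute. Family and cluster membership
enter purely as multiplicative boosts on labeled neighbors, never as a
source of candidates.

Disease similarity assumes a MeSH-style poly-hierarchy: each term's tree
numbers induce the ancestor DAG, and a term reachable by several paths is
counted once at its **minimum depth** in the layer scheme. This
min-depth rule is equivalent to the recursive formulation that takes,
per ancestor, the best (largest) product of per-edge factors over all
paths, since `Δ^depth` is monotone decreasing in path length for Δ < 1;
the test suite checks the equivalence by exhaustive path enumeration on
random DAGs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| Δ (`delta`) | 0.5 | per-layer decay of a term's semantic contribution (layer scheme); Δ = 1 flattens the DAG |
| IC base | 2 | logarithm base of information content; base 2 is the convention that makes a term present in 40 of 4577 DAGs score 6.838 |
| λ (`fusion_weight`) | 0.5 | weight of semantic vs phenotype similarity in `DS = λ·SS + (1−λ)·PS`; PS absent ⇒ `DS = SS` |
| k | 20 | neighborhood size of the scorer; unlabeled neighbors occupy slots and contribute 0 |
| α, β | 4 | family/cluster weight adjustment: `w = 1 + r/factor`, bounded in [1, 1 + 1/factor]; sending a factor to ∞ disables the boost |
| cluster gap | 20 000 bp | maximum inter-precursor interval gap for single-linkage genomic clustering (strand-agnostic) |
| `min_labels` | 60 (headline) / 8 (synthetic scale) | per-disease eligibility floor for cross-validation |

Information content is computed with one DAG per ontology term
(`N = |ontology|`, every term contains itself, so `IC ≥ 0` and a term in
every DAG has IC exactly 0). The six IC values of the worked example are
carried as *input data* in the fixture: they were produced on a full
4577-term vocabulary that this package does not bundle.

## Cross-validation and leakage

Per fold, the held-out (miRNA, disease) labels are removed from the
association store before anything downstream runs. Because the
functional-similarity matrix itself is a function of the labels, the
rows/columns of the held-out miRNAs are recomputed from the reduced
store each fold (an incremental update: entries between unchanged miRNAs
are provably identical to a full rebuild, which the tests assert).
Group rates are always evaluated against the current store, so weights
follow training labels with no extra bookkeeping. A held-out miRNA whose
disease group becomes empty gets similarity 0 to everything: with no
known associations its function carries no information. Passing
`disease_sim=None` to the evaluator skips the matrix refresh and scores
on the full-label matrix — useful for ablation, but it leaks the hidden
association into the neighborhoods.

Per-fold AUCs are averaged into a per-disease AUC (folds stay
exchangeable; pooling ranks across folds would mix candidate pools of
different compositions), and the grand mean weights diseases equally.
AUC is the Mann–Whitney pair statistic (ties ½), computed via
scikit-learn's trapezoidal `roc_curve`/`roc_auc_score`; an independent
pair-counting oracle cross-checks it in the tests.

Fold assignment is a seeded shuffle followed by round-robin dealing, so
fold sizes differ by at most one and a fixed seed reproduces the split
exactly.

## Synthetic corpora: what they emulate, and what not

`generate_corpus` plants modules: each miRNA belongs to one of 4 modules,
each module owns the 6 sibling leaves of one parent in an 8-parent ×
6-leaf two-level disease hierarchy, and associations are drawn at
`p_in = 0.8` within the module against `p_out = 0.05` background (60
miRNAs by default). Sibling leaves share a parent, guaranteeing nonzero
shared-ancestor similarity, and the generated phenotype table (75 % of
diseases mapped) reinforces the same sibling structure — so semantic,
phenotype, family and cluster channels all point at the same planted
signal. Families and clusters are module-aligned five-member groups;
cluster members are written as GFF3 loci with sub-20 kb gaps, everything
else is scattered on isolated contigs. The null corpus draws every
(miRNA, disease) pair at a flat probability — 0.2 by default, chosen so
that diseases still clear the 8-label eligibility floor at this corpus
size (the label-count arithmetic, not any measured AUC, fixed this
value; at 0.05–0.1 almost no disease is evaluable at n = 60).

Passing tests on these corpora show the pipeline recovers block
structure expressed simultaneously in ontology, phenotype and group
channels, and does not hallucinate signal from unstructured labels. They
do **not** show robustness to what real catalogs add: highly skewed
disease degree distributions, study-driven ascertainment bias,
inconsistent disease naming, miRNAs whose disease groups span modules,
or families that cut across disease neighborhoods. Headline real-data
AUCs therefore require the real HMDD/MeSH/OMIM snapshots, which are not
bundled.

A single integer seed (numpy `default_rng`) threads through every draw;
no global random state is touched, and rerunning a spec writes
byte-identical files.

## Numerical and design choices

- Similarities are clipped at 1.0 against round-off; matrices validate
  symmetry (1e-9), bounds, and a unit diagonal on construction.
- Ties everywhere — neighbor selection, candidate ranking — break by
  ascending miRNA id; ranks are dense and 1-based.
- miRNA ids normalize by trimming and lowercasing (`hsa-miR-21` ≡
  `hsa-mir-21`); disease names match case- and whitespace-insensitively,
  ids taking precedence.
- The similarity matrix diagonal is fixed at 1 by convention; neighbor
  sets exclude the query, so self-similarity never enters a score.
- A miRNA belongs to at most one family and one cluster: duplicate
  family membership keeps the first (warned), overlapping genomic chains
  are unioned. Group membership is restricted to the miRNAs of the
  association set *before* group sizes enter any rate. Singleton
  clusters are dropped — a lone member can never share its cluster with
  a neighbor, so they are weight-inert either way.
- Genomic clustering uses interval gaps (`next.start − prev.end − 1`,
  floored at 0 for overlaps), not start-to-start distances, on 1-based
  inclusive GFF3 coordinates.
- Missing phenotype data is a value, not an error: unmapped diseases
  fall back to semantic similarity, since ontology↔phenotype mappings
  are partial in practice. Multiple mappings aggregate by max, mirroring
  the best-match rule used for disease groups.
- The temporal hold-out drops (and logs) old-snapshot pairs missing from
  the new snapshot rather than failing, and skips diseases with no
  additions or no negatives.

## Problem sizes

The bundled benchmark runs 20 seeds of planted and null corpora at 60
miRNAs / 48 diseases with 5-fold cross-validation over all eligible
diseases (~24 planted, ~45 null), and the temporal-hold-out simulation
runs 20 seeds at 32 miRNAs. These sizes give stable seed-averaged AUCs
(observed spread well inside the asserted margins) while keeping the
full suite in the low minutes on one core.

## Known limitations

- The IC scheme's values depend on the vocabulary the ICTable was
  computed from; mixing an external IC table with a differently scoped
  ontology raises coverage errors rather than guessing.
- `update_similarity_rows` is quadratic in the number of changed miRNAs
  times matrix size; it is meant for the few held-out rows per fold, not
  wholesale relabeling.
- The evaluator's candidate pools treat every unlabeled miRNA as a
  negative, the standard (and pessimistic) convention when future
  positives hide among them.
- No network propagation / random-walk scoring; the ranker is strictly
  local to the k-neighborhood.
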
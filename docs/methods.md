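# Methods

## Model of the data

Each patient sample is modeled as a weighted, undirected, simple graph on
the metabolites of a genome-scale metabolic model. The topology is a
property of the model alone — which metabolites can be interconverted by a
catalyzed reaction — and is therefore identical for every sample of a
dataset; the sample enters only through edge weights, which are derived
from its gene expression. Clustering then asks whether patients fall into
groups with systematically different weight profiles on a common wiring.

### Node identity and filtering

A metabolite is identified by the pair (name, compartment): the same
chemical in two compartments plays different roles and is two nodes.
Before graph construction two filters are applied:

* **Currency metabolites** (H₂O, CO₂, ATP, NAD⁺/NADH, …) connect large
  fractions of the reaction set and would create biologically meaningless
  shortcuts, so they are deleted — matched by case-insensitive bare name
  across every compartment. The shipped default list (16 common cofactors
  and carriers) is a generic stand-in; any model-specific list can be
  supplied as a one-name-per-line text file. Reactions left without
  substrates or products by this deletion are dropped. The filter is
  idempotent.
* **Uncatalyzed reactions** (no gene association) carry no expression
  signal; since they would contribute the same structure to every sample,
  they are removed.

### Edge weights

For one reaction r with gene set G(r), substrate set S(r) and product set
P(r), and one sample, every (s, p) ∈ S(r) × P(r) with s ≠ p receives one
parallel edge per gene g ∈ G(r), weighted by the expression of g in the
sample. All substrate × product couples are generated (the natural reading
when a reaction has several substrates and products). The multigraph is
collapsed by

  w(u, v) = Σ_r mean{ weights of (u,v)-edges contributed by reaction r },

i.e. enzymes catalyzing the *same* reaction are treated as equally
important for that conversion (average), while *different* reactions
linking the same pair are alternative routes (Boolean OR, sum). Gene
handling at collapse time: an expression value of 0 is a measurement and
participates in the within-reaction mean; a gene absent from the
expression matrix is excluded from the mean's denominator; a reaction all
of whose genes are absent contributes no edges.

Reversibility is ignored: the graph is undirected, consistent with the
symmetric Laplacian and the symmetric distance used downstream.
Stoichiometric coefficients are read but only substrate/product roles are
kept — edges encode co-occurrence in a reaction, not flux.

One representational subtlety: an edge whose genes all measure 0 has
weight 0 but still *exists* structurally. `SampleGraph` therefore carries
the boolean structure matrix alongside W; the partition below is computed
on the structure, which is what makes it sample-independent. After
collapse, analysis restricts to the largest connected component of the
structure (singleton and minor components are discarded, with sizes
logged; ties are broken toward the component containing the
lexicographically smallest node id, for determinism).

## Summarization

Given the shared structure A (l × l, binary) the nodes are partitioned
into k clusters by spectral clustering with the *unnormalized* Laplacian
L = D − A, D_ii = degree(i): the eigenvectors of the k smallest
eigenvalues form the l × k feature matrix whose rows are clustered by
k-means (10 restarts, explicit seed, retry with reseeding in the rare
event of an empty cluster). The unnormalized Laplacian and the absence of
row normalization are deliberate: they follow the formulation stated for
this method rather than the normalized variants more common elsewhere.
For a connected graph L has exactly one zero eigenvalue; connectivity is
enforced as a precondition and the zero-eigenvalue count is checked as a
diagnostic. k = l degenerates to the identity partition (forced by the
requirement that no cluster be empty); k > l is an error.

With Q the l × k indicator matrix (one 1 per row), every sample's weight
matrix collapses as W_s = QᵀWQ. This conserves total weight exactly and
is linear in W. The diagonal of W_s (intra-supernode weight) is retained
and participates in supernode strength: random-walk self-transitions on a
collapsed graph are meaningful mass, and dropping them would break weight
conservation. The partition is computed once per dataset and reused for
every sample, so summarized networks remain comparable.

## The M² distance

A summarized network G_r defines per-supernode one-step random-walk
distributions: row i of W_s divided by strength(i) = Σ_j W_s[i, j]
(diagonal counted once). Equivalently, in the column-stochastic transition
matrix T with T[i, j] = W_s[i, j]/strength(j), the distribution of
supernode i is column i; because W_s is symmetric the row and column
conventions coincide after renormalization, so the ambiguity is
immaterial here (it would matter only for directed graphs, which are out
of scope). A zero-strength supernode uses the absorbing convention
(self-probability 1), which keeps every distribution valid; two absorbing
supernodes at the same index contribute 0 to the distance.

For two networks sharing a partition,

  M²(G_p, G_q) = (1/k) Σ_{i=1..k} d_JS(Tᵢᵖ, Tᵢᵠ),

with d_JS(p, q) = √J(p, q) and J the Jensen–Shannon divergence computed
with base-2 logarithms and 0·log 0 = 0. Base 2 bounds d_JS — and hence
M² — in [0, 1]. d_JS is a metric and a coordinate-wise average of metrics
is a metric, so M² is symmetric, satisfies the triangle inequality, and
vanishes exactly when all per-supernode distributions coincide. Because
each distribution is normalized by strength, multiplying every weight by a
global constant leaves M² unchanged: the distance compares expression
*profiles*, not library size. Numerically, distributions are renormalized
to sum exactly to 1 before the divergence and tiny negative round-off is
clipped at 0 before the square root. k = 1 is degenerate (every
distribution is (1)); it returns 0 with a warning.

## Sample clustering

Spectral clustering needs an affinity; the distance matrix is converted
with a Gaussian kernel A = exp(−D²/2σ²), σ defaulting to the median
off-diagonal distance (the median heuristic, overridable; an all-zero D
has no defined bandwidth and demands an explicit σ). Clustering uses the
standard normalized-Laplacian spectral pipeline on the precomputed
affinity with seeded k-means label assignment. The number of clusters is
user-supplied (the number of known classes in evaluation settings); no
model selection is attempted. Labels are canonically renumbered by first
occurrence so repeated runs are byte-identical and diffable. The
`expression` baseline applies the identical conversion and algorithm to
Euclidean distances between samples' metabolic-gene expression vectors.

## Evaluation metrics

Eight external-validation metrics, computed from the predicted/truth
contingency table (mathematically identical to direct pair enumeration,
verified against an O(n²) oracle in the tests): RI, MR = 1 − RI, F1, FMI
from the TP/FP/FN/TN pair counts; ARI via the closed-form hypergeometric
expectation; CA as the per-predicted-cluster best overlap (many-to-one);
NMI and AMI with the √(H(CP)H(GT)) normalization, entropies and MI in
nats (the base cancels in both normalizations), and E[MI] by the exact
hypergeometric summation rather than Monte-Carlo, so reported values are
deterministic. 0/0 conventions: precision/recall/F1/FMI are 0 when their
denominators vanish; single-cluster degenerate labelings yield 0 with a
warning instead of NaN. The CLI and TSV writers report all metrics ×100.

## Synthetic data

The generator emulates exactly the structure the method assumes and
nothing more: a shared topology with class-specific weight distributions.

* **Model**: a spanning backbone of sequential conversions keeps the
  metabolite graph connected, plus random 1–2-substrate × 1–2-product
  reactions; each reaction draws 1–3 genes from a pool of one symbol per
  reaction. A configurable fraction of reactions (default 5%) is left
  uncatalyzed and a few currency metabolites (default 3, drawn from the
  default exclusion list) attach to 20% of reactions, so both filters are
  exercised on every synthetic run.
* **Expression**: baseline lognormal(0, σ) per gene and sample — positive
  and right-skewed like FPKM — with σ = 0.2 by default; each class
  multiplies a disjoint 20% gene subset by the class effect (default
  ×10). Effects are placed on *genes*, not edges, so the signal must
  propagate through the construction rules exactly as in real data.
* **Cohort**: defaults of 500 metabolites, 800 reactions and 2 classes ×
  30 samples define the standard recovery study; the integration tests
  use smaller instances (60–130 reactions, 16–20 samples) of the same
  generator.

Everything is deterministic from the single spec seed (seeded NumPy
generator streams, one per stage).

What passing on synthetic data does **not** show: the generator has no
probe-level noise, no batch effects, no correlated gene modules, no
class-imbalanced cohorts, and its topology is far smaller and more
regular than a curated genome-scale model (thousands of nodes, heavy-
tailed degrees). Results on it validate the machinery and its
statistical behavior, not performance on any real cohort.

## Problem sizes and numerical choices

The bundled studies run at desk scale by design: recovery at 500
metabolites/60 samples/k = 50, metric-axiom checks on 1000 random triples
with k ≤ 10, oracle agreement on 10⁴ distribution pairs and 500 labeling
pairs with n ≤ 200. Dense eigensolvers (`scipy.linalg.eigh` with an
eigenvalue-index window) are used for the Laplacian: the shared topologies
here are a few thousand nodes at most, where the dense path is simpler and
more robust than sparse iteration. Tolerances: column-stochasticity and
conservation at 1e−9, oracle agreement at 1e−12, Laplacian zero-eigenvalue
threshold 1e−8.

## Known limitations

* SBML reading goes through cobrapy and inherits its dialect coverage;
  gene-association boolean trees are flattened to gene sets (the
  within/between-reaction averaging is the only AND/OR semantics applied).
* Directed metabolic networks are unsupported; the row/column convention
  of the transition matrix would then need to be fixed explicitly.
* The distance-to-affinity conversion ahead of sample clustering is a
  choice (Gaussian kernel, median σ); other conversions would give
  slightly different clusterings.
* No automatic selection of either the supernode count k or the number of
  sample clusters; k is swept (default 50–300) and the cluster count is
  supplied by the user.
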
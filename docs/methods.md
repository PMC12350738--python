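# Methods

## Graph model and its assumptions

A molecule is represented by its hydrogen-suppressed graph: vertices are
heavy atoms, edges are bonds, and a double bond is the same edge as a
single bond (duplicate edges collapse with a warning rather than an
error, because bond-order-annotated inputs legitimately repeat pairs).
Hydrogen suppression is the caller's responsibility: the library computes
on the graph it is given, verbatim. This convention was adopted because it
is the one under which the packaged drug table's index columns are
reproducible from the structures — verified by hand-encoding
acetaminophen, metformin, ibuprofen, gabapentin and cephalexin and
recovering every index cell exactly.

Vertex labels are opaque strings; no element or valence semantics are
enforced. Disconnected graphs are accepted with a warning: every index is
an edge sum, so isolated vertices contribute nothing and the values remain
well-defined.

## Exact arithmetic

All coefficients are affine-rational expressions `c0 + c1·t` over
`fractions.Fraction`, where `t` is an optional formal repeat parameter.
One formal parameter suffices for every polymer family treated here, and
the operator calculus only ever scales and shifts coefficients — so the
product of two parameter-dependent expressions is deliberately undefined
and raises. Floating point appears in exactly two places: the general
Randić index with a non-integer exponent (where per-edge values such as
(i·j)^(−1/2) are irrational), and the presentation layer, which renders
values to 4 decimal places.

## Dual-route index computation

Every index is computed both as a per-edge kernel sum over the degree-pair
partition and as the literal operator pipeline on the M-polynomial. The
two routes share no code beyond the partition itself, and the test suite
requires exact agreement on seeded random graphs as well as on the
hand-encoded structures. Design choices:

* **AZI on a (1,1) edge is an error**, raised by the kernel (zero
  denominator) and independently by the pipeline (the Q₋₂ shift produces a
  constant term that the subsequent integration rejects). Silently
  skipping such an edge would corrupt cross-molecule comparisons.
* **Fractional Randić exponents are kernel-only.** The pipeline form
  D_x^α D_y^α is implemented for integer α (negative integers via the
  integral inverses); non-integer α raises with a pointer to the kernel
  route. Default α = −1/2, the classic Randić index.
* **SDD** is computed as Σ count·(i²+j²)/(i·j); the algebraically equal
  form Σ count·(i/j + j/i) is used by the independent test oracle.

## Polymer closed forms and the audit

The built-in families are defined by their published edge partitions —
dextran `{(1,3): 11s+2, (3,3): 16s, (2,3): 17s−2, (2,2): 3s−1, (1,2): s}`
and chitosan `{(1,2): 2p, (1,3): 4p+1, (2,2): 1, (2,3): 10p−2, (3,3): 8p−1}`
— not by their published closed forms. Closed forms are always *derived*
from the partition by the kernel sum; the published coefficient pairs act
purely as audit oracles. This direction matters because the published
material is internally inconsistent in two places: the dextran symmetric
division closed form (printed slope 871/2 vs the partition's 114 — the
intermediate terms 1100/3 and 85/3 in the printed derivation appear
miscomputed) and one intermediate term of the dextran ReZG₃ derivation
(84x²y², inconsistent with 16·3 = 48, though the stated final value does
match the partition). The audit reports MATCH/DISCREPANT per index with
both values shown; it never adopts either side of a discrepancy as "the"
truth. The partitions themselves are trusted because they also reproduce
the per-drug index logic of the packaged table. Custom families can be
supplied as a CSV of `(i, j, c0, c1)` rows without code changes.

The chitosan family's published general-Randić expression is not a
well-formed index formula and is excluded from the audit; Rα for the
families is available through the kernel route (integer α exact,
otherwise evaluate the partition at concrete parameter values).

## The packaged drug table

`mpolykit/data/drug_table.csv` holds 45 polycyclic drugs: identifiers
(PubChem CID, ChemSpider ID), eleven index columns and twelve property
columns, transcribed from a published table set (see
`docs/drug_table.md` for the column dictionary and the transcription
provenance notes). Two columns, `Sch` and `Gut`, have no published
definition; they are carried as opaque data, never used as defaults, and
excluded from computed-index checks. Property units are carried exactly as
printed, without conversion. The loader verifies a SHA-256 checksum so a
corrupted installation fails loudly.

## QSPR study design

* **Models**: OLS, ridge (penalty 1.0), lasso (penalty 0.1), elastic net
  (penalty 0.1, mixing 0.5), SVR (RBF kernel, C = 1.0, ε = 0.1). The
  source study names these five families without printing hyperparameters,
  fold assignments or split seeds, so the defaults here are this package's
  own choices, all config-exposed; agreement with the source is assessed
  qualitatively (which model family is strong for which property), never
  cell-by-cell.
* **Predictors** default to {ᵐM₂, ReZG₃} because every published final
  equation uses exactly those two; any column subset is selectable.
* **Standardization**: predictors are standardized on training-partition
  statistics before regularized fits; linear coefficients are reported
  back on the raw scale.
* **Cross-validation**: k = 5 shuffled folds; metrics are computed on the
  *pooled* out-of-fold predictions (a per-fold-average alternative exists
  in the literature but is not printed in the source; pooled was chosen
  and is documented here). R is Pearson(observed, predicted), R²_corr its
  square (always in [0, 1]), R² the coefficient of determination
  1 − SSres/SStot (can be negative out of sample), RMSE on the same pooled
  vector, and the p-value the two-sided t-test on R with n − 2 degrees of
  freedom.
* **External validation**: a 20% hold-out split; the model is refit on the
  training partition only.
* **Correlation heatmap**: signed Pearson r with two-sided p-values and
  significance stars (* p<0.05, ** p<0.01, *** p<0.001). The display
  convention of clipping negative r to zero is available as a transform;
  the returned matrix always keeps signs. On the packaged table every
  index–property correlation happens to be non-negative, so clipping is a
  no-op there.

### A note on permutation nulls under pooled CV

With a permuted target, pooled out-of-fold predictions are systematically
*anti*-correlated with the observations (each fold's model chases the
other folds' noise, and predictions regress toward fold means), so the
two-sided p-value on Pearson r can be small even with zero signal. The
permutation-control tests therefore check what permutation actually
destroys — predictive skill (R²_cv collapses to ≈ 0 or below) and the
*median* p over many permutations — rather than requiring every
single-permutation p to exceed 0.05.

## Synthetic data

`random_molecular_graph(n, max_degree, seed)` grows a random tree by
degree-capped attachment and adds sparse ring-closing edges, yielding
connected simple graphs with all degrees in [1, max_degree] — the shape of
hydrogen-suppressed organic molecules (default cap 4). It emulates degree
structure only: no element identities, no realistic ring statistics, no
bond-order information. Tests on these graphs therefore validate the
*combinatorics and calculus* (route equivalence, handshake and partition
invariants, format round-trips), not chemical realism; chemical ground
truth enters through the hand-encoded drug structures. Synthetic
regression tables (exact linear data, noisy linear data at
signal-to-noise ≈ 10 on the real predictor columns) play the analogous
role for the statistics.

## Problem sizes and numerical choices

Route-equivalence and bookkeeping properties run over 100 seeded random
graphs with n up to 40 vertices; parameter recovery uses 100 seeded
replicates at n = 45; the permutation suites use 10 and 50 permutations.
Exact comparisons are used wherever both sides are rational; float
comparisons use an absolute tolerance of 1e−9, except against printed
4-decimal table cells, where the tolerance is the rounding radius.
Polynomial terms with zero coefficients are dropped eagerly, and partition
keys are normalized to i ≤ j at construction, so term order and renderings
are deterministic.

## Known limitations

* No SMILES/InChI ingestion: inputs are edge lists or adjacency matrices.
* Distance- and spectrum-based indices (Wiener, Schultz, Gutman, …) are
  out of scope; the `Sch`/`Gut` data columns are opaque.
* The polymer registry covers index computation only; it does not
  reconstruct atom-level repeat-unit graphs.
* The QSPR study is an analysis of a fixed 45-row table; with two
  predictors and n = 45 it is a demonstration of methodology, not a
  validated predictive model for unseen chemistry.
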
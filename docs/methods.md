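# Methods

## Scope and model

`phytorank` implements a degree-based virtual-screening workflow for small
phytochemical libraries, exercised end to end on a bundled eleven-compound
neem (*Azadirachta indica*) study set: azadirone, azadirachtin,
stigmasterol, tiglic acid, catechin, scopoletin, odoratone, tirucallol,
nimbin, nimbolide and sugiol.

A molecule is reduced to its hydrogen-suppressed skeleton: vertices are
heavy atoms, edges are covalent connections, and bond order is ignored (a
double bond is one edge). The degree d(v) of a vertex is therefore its
heavy-atom neighbour count. This convention is forced by verification: the
first Zagreb index of the tiglic acid skeleton equals the reference value
26 only under hydrogen suppression with unit bond multiplicity, so the
convention is applied globally.

All ten topological indices are sums over edges of a symmetric function of
the two endpoint degrees. The edge partition — the multiset of sorted
endpoint-degree pairs with multiplicities — is therefore a sufficient
statistic, and every index is computed as `sum(count * term(i, j))` over
partition classes, visited in sorted class order so floating-point results
are reproducible. A per-edge brute-force summation (no partition) serves
as the independent oracle in the test suite.

Two caveats inherited from the reference tables are handled explicitly
rather than papered over:

* **ISLI**: the printed defining formula of the inverse sum lordeg index
  is identical to that of the inverse sum indeg index (ISI), yet reference
  tables list distinct values for the two columns. We implement the
  printed formula literally and keep ISLI a separate identifier, so
  decision matrices transcribed from published tables retain their ISLI
  column. The variant that produced the published ISLI values cannot be
  determined from the formulas alone.
* **Printed-value discrepancies**: for tiglic acid — the one skeleton
  small enough to check by hand — M1 (26), MDI (8) and ABC (4.53)
  recompute exactly, while the printed ISI (5.7 vs 5.6167 by the formula)
  and RLI (1.6684 vs 1.9685 = ln2·ln3 + (ln3)²) do not. Tests assert the
  formula values against the brute-force oracle; the printed entries are
  recorded here as discrepancies, not used as targets.

The augmented Zagreb term divides by `i + j - 2` and is undefined on an
edge joining two degree-1 vertices (e.g. a two-atom molecule). Such graphs
are rejected with a hard error: silently dropping the edge would corrupt
comparability across indices.

## QSPR regression

Properties (enthalpy of vaporization kJ/mol, boiling point °C,
polarizability Å³, molar refractivity cm³, monoisotopic mass Da) are
regressed on each index with ordinary least squares in linear
(`PC = A + B·TI`) and quadratic (`PC = A + B·TI + C·TI²`) form,
via statsmodels. Statistical metrics per fit: N, R, R², the F statistic
and its p-value. Conventions where the literature is loose:

* Missing cells (the study set's catechin enthalpy) are removed by
  listwise deletion per property–index pair, so enthalpy fits use N = 10
  while all other properties use N = 11.
* R is reported as sign(B)·√R² for linear fits; for quadratic fits, where
  a signed slope convention has no analogue, R is the Pearson correlation
  between fitted and observed values.
* A fit is admissible when p < 0.05 and R ≥ 0.6; the best model per
  property is the admissible fit maximizing R². Maximization is the only
  selection rule consistent with reporting a single best pairing per
  property.
* No multiple-testing correction is applied across the 5 × 10 grid; the
  screen is exploratory and the reference workflow applies none either.

On the bundled tables the best linear model for boiling point is RLI
(R² ≈ 0.8382) and the best quadratic model for monoisotopic mass is RLI
(R² ≈ 0.9795).

## Multi-criteria ranking

The decision matrix defaults to the published table of six index criteria
(ABC, AUZ, RLI, SLI, MDI, ISLI) for the eleven compounds, with weights
(0.2, 0.1, 0.3, 0.1, 0.2, 0.1). All six criteria are treated as
beneficial; orientation flags exist for cost-type criteria. The CLI's
`--use-recomputed-indices` flag swaps in indices recomputed from the
bundled skeletons, which shifts the columns affected by the printed-value
discrepancies above — hence the printed matrix is the default, so
published reference rankings reproduce exactly.

**VIKOR**: each cell is normalized to `w·(A* − x)/(A* − A−)` where A*/A−
are the per-criterion best/worst. Group utility S is the row sum, regret R
the row max, and the compromise index
`Ω = λ(S−S*)/(S−−S*) + (1−λ)(R−R*)/(R−−R*)` with λ = 0.5 by default
(exposed as a parameter). Rank 1 is the smallest Ω. The classical
acceptable-advantage/acceptable-stability conditions are out of scope. A
criterion whose column is constant, or a matrix whose alternatives all tie
in both S and R, is rejected — the normalizations are undefined there.

**SAW**: columns are normalized and weighted, totals summed per
alternative, rank 1 the largest. The default normalization divides by the
column maximum: although vector normalization (column Euclidean norm) is
the textbook phase-2 formula, only max-normalization reproduces the
published normalized matrix (the top compound's row is all 1.0000), so
`max` is the default and `vector` an option.

**Concordance**: Spearman's ρ is implemented from the tie-free closed form
`1 − 6Σδ²/(N(N²−1))`; it is not a tie-corrected estimator. Ties in Ω or
totals receive competition ranks (ties share the smaller rank); the study
set has none. On the bundled matrix the two methods disagree only by the
adjacent swap of catechin and sugiol, giving Σδ² = 2 and ρ ≈ 0.9909
(published as 0.98, which we treat as a lower bound).

Printed-table comparisons in tests use absolute tolerance 5e-4 for entries
printed to four decimals and 5e-5 for five-decimal entries.

## Bundled fixtures

Edge-list skeletons for the eleven compounds were frozen from SMILES
encodings of the published structure depictions (neutral PubChem forms).
The tiglic acid skeleton is unambiguous; the ten larger skeletons are
best-effort reconstructions whose molecular formulas match the reported
monoisotopic masses (e.g. azadirachtin C35H44O16), and their edge-file
headers say so. Consequently only tiglic acid's index values are asserted
against the reference index table; the ranking and regression stages use
the published tables directly, which is also why those stages reproduce
the published numbers regardless of skeleton fidelity.

## Synthetic data

Generators mirror the structure the pipeline assumes, fully determined by
a seed:

* **Graphs**: a uniform random labelled tree (Prüfer sequence,
  rejection-sampled until all degrees ≤ max_degree, default 4) plus
  `round(f·(n−1))` extra edges drawn uniformly among non-adjacent pairs
  with both endpoint degrees below the cap. Trees on ≥ 3 vertices never
  contain a degree-(1,1) edge, so generated graphs always satisfy the
  augmented-Zagreb precondition. Defaults: 20 vertices (mid-range of the
  study's 7–51 heavy atoms), extra-edge fraction 0.15 (a few rings per
  molecule, typical of small natural products).
* **Properties**: `PC = A + B·TI + C·TI² + ε`, ε ~ N(0, σ²) homoscedastic
  — the generative inversion of the OLS model, which implicitly assumes
  exactly this noise.
* **Decision matrices**: positive lognormal entries with per-criterion
  scales; optionally one alternative rescaled to dominate every criterion
  (both methods must then rank it first). Weights are symmetric-Dirichlet
  draws rounded to sum exactly to one.

What the generator does **not** emulate: element identities, valence
bookkeeping beyond the degree cap, bond orders, correlated or
heteroscedastic property noise, and correlated criteria. Passing tests
therefore demonstrate correctness of the computations and selection logic
under the stated assumptions, not predictive validity of QSPR models on
real chemical space.

The planted-recovery test draws library sizes from 8–40 vertices,
mirroring the study compounds' size range; between-compound index spread
is what makes the planted predictor identifiable among ten collinear
indices.

## Numerical choices and problem sizes

* Per-class index aggregation in sorted class order; oracle comparisons at
  1e-12 relative.
* OLS through statsmodels; coefficients checked against the
  normal-equation solution at 1e-8 relative in tests.
* Competition ranks via `scipy.stats.rankdata(method="min")`.
* Weight validation at 1e-9 absolute on the unit sum.
* Test-suite simulation sizes: 200 random graphs (≤ 30 vertices) for the
  index oracle; 200 seeded trials for planted-model recovery; 500
  replicates at n = 200 for OLS interval coverage — sizes chosen to make
  Monte-Carlo bands (e.g. coverage in [0.93, 0.97]) tight enough to be
  meaningful while the whole suite stays interactive.

## Known limitations

* Only degree-based indices; no distance-based, eigenvalue or polynomial
  descriptors.
* The SMILES adapter requires RDKit and performs no tautomer or
  protonation normalization; fixtures follow neutral forms.
* `spearman_rho` assumes tie-free rankings.
* Weights are inputs, never derived: no elicitation procedure is
  implemented because none is specified for the reference weights.
* The ten large bundled skeletons are reconstructions (see above); treat
  their recomputed indices as illustrative, not reference values.
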
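# Methods

## Statistics and conventions

All statistics are plug-in computations on population allele frequencies:
`F2(a,b) = (1/S)Σ_l (x_al − x_bl)²`, `F3` and `F4` the corresponding
scaled dot products of difference vectors. The `1/S` normalisation uses
the full SNP count for every statistic (missing data is not representable
at this layer, so no per-statistic SNP counts arise). No finite-sample
bias correction is applied; bias-corrected F2 matrices estimated by
external tools can be supplied as input (`F2Matrix` with
`source="external"`) and carried through the same machinery. Monomorphic
or population-invariant SNPs are retained — they contribute zero to every
statistic and keep `S` interpretable.

`f4_from_f2` uses the identity `2F4(a,b;c,d) = F2(a,d)+F2(b,c)−F2(a,c)
−F2(b,d)`, which is what expanding the dot product in squared norms
gives; test suites verify it against the direct definition at 1e-12.

## The PCA link

The decomposition scales the centred data by `1/√S` before the SVD, so PC
coordinates are in F2 units: `Σ_k (p_ik − p_jk)² = F2(i,j)` with no extra
constants, and the data route (SVD of `Y/√S`) and the F2 route
(eigendecomposition of `−½ C F₂ C`, classical MDS) are directly
comparable. SNPs are not variance-scaled: the decomposition is chosen to
match the F-statistic metric, not the individual-genotype PCA convention.

Numerical choices:

- **Sign convention.** Each PC is flipped so its largest-magnitude
  coordinate is positive; ties resolve to the lowest population index.
  This makes outputs reproducible across LAPACK builds.
- **Clamping.** In the F2 route, eigenvalues within `1e-9 ×` the largest
  magnitude of zero are treated as round-off and set to exactly zero;
  strictly more negative ones (possible only for estimated, non-Euclidean
  F2 input) are clamped to zero and counted in `n_clamped`. The
  distinction separates numerical noise from genuine non-Euclidean
  structure.
- **Symmetrisation.** F2 matrices are symmetrised (`(m + mᵀ)/2`) before
  double-centring, absorbing decimal round-trips through TSV files; the
  file reader rejects asymmetry beyond `1e-8` relative as a real error.
- **K_max.** At most `n − 1` PCs are kept (centring removes one
  dimension); the data route additionally caps at `S`.

`f2_frobenius_error(m, K)` is computed as the Frobenius norm of the
difference between the full-coordinate and first-K-coordinate squared
distance matrices, i.e. the root sum of squared per-pair truncation
errors. For computed (Euclidean) F2 this equals `‖F₂ − F̂₂^(K)‖_F`; for
clamped external input it deliberately measures truncation error only,
so it is exactly zero at `K = K_max` in all cases.

## Projection of new samples

With stored loadings `L` and SNP means, a complete new sample projects as
`(x − μ)/√S · Lᵀ`; the squared reconstruction residual is the projection
error, an F2 in the same units. Because the residual is orthogonal to the
loading span, `F2(X_i, X_new)` splits exactly into (first-K part) +
(truncation remainder) + (projection error).

With missing loci, coordinates solve an ordinary least squares fit of the
observed centred values on the observed loading columns. This generalises
the common remove-and-rescale recipe and reduces to it when the loadings
restricted to the observed loci are near-orthogonal; the error term is
then accumulated over observed loci only (still divided by the full `S`,
keeping units comparable), and the orthogonal three-part split no longer
applies — requesting it for a masked projection is an error rather than a
silently wrong number.

## Geometric diagnostics

- **Admixture ball.** `F3(t;a,b) = ‖t − m‖² − F2(a,b)/4` with `m` the
  midpoint of the sources, so the sign classifies the target against the
  ball with diameter `ab`. The `on_sphere` band is `|F3| < 1e-12`
  absolute; otherwise classification is by strict sign.
- **Projected-circle guarantee.** The flag `outside_projected_circle`
  tests the target's subspace coordinates against the projection of the
  *full* ball — centre at the projected midpoint, radius `√F2(a,b)/2`.
  Only that radius carries the guarantee "outside on any projection ⇒
  F3 > 0": the smaller circle through the projected sources (also
  reported, as `CircleRegion.radius`) can be escaped by targets whose F3
  is negative on higher PCs. Boundary points count as not-outside
  (conservative with respect to the guarantee).
- **F4-ratio.** The formula `α = F4(R1,R2;X,X1)/F4(R1,R2;X2,X1)`
  evaluates to the coefficient of `X2` in a drift-free mixture (`α = 0`
  at `X = X1`, `α = 1` at `X = X2`); it is documented and printed as the
  X2-side share, with `1 − α` printed alongside as the X1 share. The
  denominator must exceed `1e-12 ×` the relevant F2 scale, otherwise the
  references are declared uninformative (error, not a huge ratio).
- **Orthogonality test.** A convenience wrapper returning F4 and
  `cos φ` with a caller-chosen tolerance. A pair of *identical labels*
  yields an exactly-zero difference vector: F4 = 0 and the pair is
  reported orthogonal; distinct labels with coinciding frequencies leave
  the angle undefined and raise a degeneracy error instead.
- **Residual rotation.** Populations get a signed position along the unit
  reference axis plus a PCA of the orthogonal residual. Axis-position
  differences are `F4(R2,R1;·,·)/√F2(R1,R2)`, so ratios of axis distances
  equal F4-ratio estimates; a drift-free mixture is collinear with its
  sources in both views.

## The synthetic-fixture simulator

The simulator emulates allele frequencies evolving on a rooted tree or
admixture graph: root frequencies i.i.d. per SNP (default uniform(0.1,
0.9), keeping frequencies off the boundaries), drift per edge, admixture
children formed as the weighted average of their parents *before* any
drift on their outgoing branches — mirroring the distinction between the
unobserved mixing population and the sampled, drifted one.

Two drift models are provided because the appropriate choice depends on
use: `gaussian_truncated` (default) adds `Normal(0, τ·p(1−p))` per locus
and clips to [0,1] — τ is branch length in drift units and analytic
expectations are available; `binomial_wright_fisher` draws
`Binomial(N, p)/N` with `N = round(1/τ)` as a discrete sanity check.
Clipping introduces a small bias that is negligible at the default root
distribution and `τ ≤ 0.05`.

`expected_f2` gives the first-order expectation for admixture-free
graphs: each edge on the leaf-to-leaf path contributes `τ_e · E[p(1−p)]`,
with the heterozygosity evaluated under the root distribution (closed
form for uniform and beta) and treated as constant along the path. The
approximation error is of order the total drift; simulations at
`S = 100,000` and `τ ≤ 0.02` match within a few percent. The function
takes the `SimConfig` alongside the graph because the root distribution
determines the heterozygosity constant.

Reproducibility: each node's random stream is seeded by hashing the
global seed with the node label (SHA-256), so identical (graph, config)
pairs give bit-identical output and editing one branch never reshuffles
drift elsewhere.

What the simulator does *not* emulate: linkage between SNPs, mutation,
selection, coalescent noise from finite samples of individuals, and SNP
ascertainment. Passing tests therefore demonstrate the mathematical
identities and the statistical behaviour of drift-structured frequencies,
not robustness to the sampling noise and ascertainment of real panels —
for real data, externally estimated (bias-corrected) F2 matrices are the
intended entry point.

## Problem sizes used in the checks

The verification suite runs at desk scale, chosen so each property is
measured well beyond its tolerance: 500 random matrices (n ≤ 8, S ≤ 200)
for the exact identities; 100 draws for rotation invariance and route
equivalence; 10,000 random triples for the ball theorem and 10,000
randomized higher-PC completions for the projected-circle guarantee; 200
replicates at S = 10,000 per admixture proportion (0.1/0.3/0.5) for
F4-ratio recovery; 50 replicates at S = 100,000 for the four-taxon
treeness check and the simulator's closed-form calibration (expected
two-leaf F2 = 0.004933 for τ = 0.01 + 0.01 and a uniform(0.4, 0.6) root).

## Known limitations

- Plug-in statistics only: no block-jackknife standard errors or Z-scores;
  significance testing is out of scope.
- The missing-data projection is a least-squares fit, not the
  shrinkage-corrected projection used by some genotype-PCA tools; for
  high missingness the coordinates are noisier than a corrected method's.
- `expected_f2` is first-order in total drift and undefined for admixture
  graphs.
- Individual-level, variance-scaled PCA is a different convention from
  the frequency-space decomposition used here; results are comparable
  only qualitatively.
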
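# fstatpca

F-statistics (f2, f3, f4) and their geometric interpretation in PCA space,
for population-level allele-frequency data.

## The problem

F-statistics *sensu* Patterson and principal component analysis are the two
workhorses of population-structure analysis, especially in human ancient-DNA
work — yet they are usually treated as unrelated summaries. They are not.
Writing each population as a point `X_i ∈ [0,1]^S` of allele frequencies at
`S` biallelic SNPs,

    F2(a, b)       = (1/S) ‖X_a − X_b‖²                    (squared distance)
    F3(t; a, b)    = (1/S) ⟨X_t − X_a, X_t − X_b⟩          (dot product)
    F4(a, b; c, d) = (1/S) ⟨X_a − X_b, X_c − X_d⟩          (dot product)

and PCA of the centred frequency matrix is exactly classical
multidimensional scaling of the pairwise-F2 matrix:

    P Pᵀ = −½ C F₂ C        (C the centring matrix, P the PC coordinates)

Because dot products are rotation invariant, **every F-statistic is a sum of
per-PC contributions**, and truncating to the first K PCs gives the optimal
rank-K approximation of `F₂` with an explicit, non-negative (for F2)
remainder. This turns familiar statistics into pictures and back:

- **Admixture-F3**: `F3(t; a, b) < 0` exactly when `t` lies inside the
  n-ball whose diameter joins `a` and `b`. On a 2-PC plot the ball projects
  to a circle; a point *outside* the projected full-radius circle on any
  plot is guaranteed to have `F3 > 0`.
- **Outgroup-F3**: `F3(O; U, X_i)` is the projection of `X_i − O` onto the
  axis `O → U`; ranking a panel by F3 ranks it along that axis.
- **F4 as an angle**: `F4/√(F2·F2) = cos φ`, the correlation between two
  drift vectors; tree-like (independent) drifts are orthogonal (φ = 90°).
- **F4-ratio**: `α = F4(R1,R2;X,X1)/F4(R1,R2;X2,X1)` is a ratio of projected
  lengths on the reference axis and estimates an admixture proportion.

The package computes all of the above from a frequency table, an EIGENSTRAT
geno/ind/snp triple, or an externally estimated F2 matrix, projects new
samples onto a reference PCA with an explicit projection error, and ships a
drift simulator for trees and admixture graphs so everything is testable
without external data.

## Worked example

Simulate a five-population admixture graph in which `XX` derives 30% of its
ancestry from the `X2` side (and 70% from `X1`), with drift after admixture:

```python
from fstatpca import (GraphSpec, SimConfig, simulate, pca_from_data,
                      FStatRequest, fstat_truncated, classify_f3, f4_ratio, f3)

graph = GraphSpec(
    nodes=("root", "O", "n", "X1", "p", "X2", "R2", "mix", "XX"),
    edges=(("root", "O", 0.05), ("root", "n", 0.02), ("n", "X1", 0.02),
           ("n", "p", 0.02), ("p", "X2", 0.02), ("p", "R2", 0.02),
           ("mix", "XX", 0.01)),
    admixture_events=(("mix", "X2", "X1", 0.3),),   # mix = 0.3·X2 + 0.7·X1
    leaves=("O", "R2", "X1", "X2", "XX"),
)
freqs, _ = simulate(graph, SimConfig(n_snps=50000, seed=1))

print(round(f3(freqs, "XX", "X1", "X2"), 6))          # -0.000485
d = pca_from_data(freqs)
t = fstat_truncated(d, FStatRequest("f2", ("X1", "X2")), K=2)
print(round(t.total, 6), round(t.approx, 6))          # 0.011374 0.00801
cls = classify_f3(freqs, d, "XX", "X1", "X2", subspace=(1, 2))
print(cls.position)                                   # inside_ball
r = f4_ratio(freqs, "O", "R2", "XX", "X1", "X2")
print(round(r.alpha, 4))                              # 0.304
```

The negative F3 flags `XX` as admixed; geometrically it sits inside the
ball spanned by `X1` and `X2` (`inside_ball`). The first two PCs carry
0.00801 of the total F2(X1, X2) = 0.011374, the rest living on higher PCs.
The F4-ratio recovers the simulated admixture proportion (`alpha = 0.304`
for a true X2 share of 0.3), using the outgroup `O` and `R2` as references.

The same operations are available from the shell, one subcommand per
construct (`fstatpca simulate | f2-matrix | fstat | pca | spectrum |
truncate | circle | classify-f3 | outgroup-f3 | angle | ratio | rotate |
project | plot`); run `fstatpca --help`.

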
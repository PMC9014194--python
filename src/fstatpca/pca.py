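"""The duality between PCA on allele frequencies and the pairwise-F2 matrix.

Two routes to the same principal components:

* **data route** — centre the n x S frequency matrix X over populations,
  scale by 1/sqrt(S) and take an SVD; PC coordinates are U*Sigma.
* **F2 route** — double-centre the pairwise F2 matrix (classical
  multidimensional scaling), P P^T = -1/2 C F2 C, and eigendecompose.

The 1/S factor of the F-statistics is folded into the decomposition (the
centred data is divided by sqrt(S) before the SVD), so PC coordinates are
in F2 units: for every pair, sum_k (p_ik - p_jk)^2 = F2(i, j) exactly.
Because the dot product is rotation invariant, every F-statistic can be
re-expressed as a sum of per-PC contributions; truncating to the first K
PCs yields the optimal rank-K approximation of the F2 matrix, with an
explicit, non-negative (for F2) truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CapabilityError,
    DegeneracyError,
    LabelError,
    ValidationError,
)
from .freqs import AlleleFreqMatrix, FStatRequest
from .fstats import F2Matrix

__all__ = [
    "PCDecomposition",
    "FStatSpectrum",
    "TruncatedFStat",
    "ProjectedSample",
    "ProjectedF2Parts",
    "center",
    "pca_from_data",
    "pca_from_f2",
    "fstat_spectrum",
    "fstat_truncated",
    "f2_frobenius_error",
    "project_sample",
    "f2_with_projected",
]

#: eigenvalues within CLAMP_RTOL * largest magnitude of zero are round-off;
#: anything more negative is genuine non-Euclidean structure and is clamped.
CLAMP_RTOL = 1e-9


@dataclass
class PCDecomposition:
    """PC coordinates of n populations, in F2 units.

    ``coords`` is n x K_max (K_max <= n - 1); ``eigenvalues`` are the
    squared singular values of the scaled centred data, sorted descending.
    ``loadings`` (K_max x S, orthonormal rows) and ``snp_means`` are only
    available from the data route; the F2 route cannot recover them.
    ``n_clamped`` counts negative eigenvalues set to zero (only possible
    for externally estimated, non-Euclidean F2 input).
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    pop_labels: tuple[str, ...]
    loadings: np.ndarray | None = None
    snp_means: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.pop_labels = tuple(str(p) for p in self.pop_labels)
        self._index = {p: i for i, p in enumerate(self.pop_labels)}

    @property
    def n_pops(self) -> int:
        return self.coords.shape[0]

    @property
    def k_max(self) -> int:
        return self.coords.shape[1]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise LabelError(f"unknown population label: {label!r}") from None

    def coords_of(self, label: str) -> np.ndarray:
        return self.coords[self.index(label)]


@dataclass(frozen=True)
class FStatSpectrum:
    """One F-statistic split into its per-PC contributions c_k."""

    request: FStatRequest
    contributions: np.ndarray
    total: float


@dataclass(frozen=True)
class TruncatedFStat:
    """F-statistic approximated with the first K PCs plus its remainder."""

    request: FStatRequest
    K: int
    approx: float
    error: float
    total: float


@dataclass(frozen=True)
class ProjectedSample:
    """A new sample projected onto an existing decomposition.

    ``projection_error_f2`` is the F2 between the sample and its
    reconstruction from the loadings — the part of the sample orthogonal
    to the space spanned by the reference populations.
    """

    coords: np.ndarray
    projection_error_f2: float
    observed_mask: np.ndarray


@dataclass(frozen=True)
class ProjectedF2Parts:
    """F2 between a reference population and a projected sample, split into
    (first-K truncated part) + (truncation remainder) + (projection error)."""

    truncated: float
    remainder: float
    projection_error: float

    @property
    def total(self) -> float:
        return self.truncated + self.remainder + self.projection_error


def center(freqs: AlleleFreqMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centre the frequency matrix over populations.

    Returns the centred matrix Y (y_il = x_il - mu_l, unscaled) and the
    per-SNP means mu; every column of Y sums to zero.
    """
    mu = freqs.values.mean(axis=0)
    return freqs.values - mu, mu


def _fix_signs(coords: np.ndarray, loadings: np.ndarray | None) -> None:
    """Deterministic sign convention, in place.

    Each PC is flipped so that its largest-magnitude coordinate is
    positive; ties resolve to the lowest population index (argmax picks
    the first maximum). Keeps outputs reproducible across LAPACK builds.
    """
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
            if loadings is not None:
                loadings[k] = -loadings[k]


def pca_from_data(
    freqs: AlleleFreqMatrix, want_loadings: bool = True
) -> PCDecomposition:
    """PC decomposition by SVD of the centred, 1/sqrt(S)-scaled data.

    Coordinates are U*Sigma of the SVD of Y/sqrt(S), so distances between
    coordinate rows are in F2 units. At most n-1 eigenvalues are nonzero
    (centring removes one dimension). With ``want_loadings`` the
    orthonormal SNP loadings L and the SNP means are retained, enabling
    reconstruction (coords @ loadings = Y/sqrt(S)) and sample projection.
    """
    if freqs.n_pops < 2:
        raise DegeneracyError("PCA needs at least two populations")
    y, mu = center(freqs)
    ys = y / np.sqrt(freqs.n_snps)
    u, s, vt = np.linalg.svd(ys, full_matrices=False)
    k_max = min(freqs.n_pops - 1, freqs.n_snps)
    coords = (u[:, :k_max] * s[:k_max]).copy()
    eigenvalues = s[:k_max] ** 2
    loadings = vt[:k_max].copy() if want_loadings else None
    _fix_signs(coords, loadings)
    return PCDecomposition(
        coords=coords,
        eigenvalues=eigenvalues,
        pop_labels=freqs.pop_labels,
        loadings=loadings,
        snp_means=mu if want_loadings else None,
        n_clamped=0,
    )


def pca_from_f2(m: F2Matrix) -> PCDecomposition:
    """PC decomposition from the pairwise F2 matrix (classical MDS).

    Eigendecomposes -1/2 C F2 C (input symmetrised first to absorb file
    round-trips). Eigenvalues within ``CLAMP_RTOL`` of zero (relative to
    the largest magnitude) are set to exactly zero as round-off; strictly
    more negative ones — possible only for estimated, non-Euclidean F2 —
    are clamped to zero and counted in ``n_clamped``. Loadings are not
    recoverable from F2 alone, so the result cannot project new samples.
    """
    v = 0.5 * (m.values + m.values.T)
    n = v.shape[0]
    if n < 2:
        raise DegeneracyError("PCA needs at least two populations")
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * (c @ v @ c)
    b = 0.5 * (b + b.T)
    w, vecs = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, vecs = w[order], vecs[:, order]
    tau = CLAMP_RTOL * max(float(np.abs(w).max()), 1e-300)
    n_clamped = int(np.sum(w < -tau))
    w[np.abs(w) < tau] = 0.0
    w[w < 0.0] = 0.0
    k_max = n - 1
    w = w[:k_max]
    coords = (vecs[:, :k_max] * np.sqrt(w)).copy()
    _fix_signs(coords, None)
    return PCDecomposition(
        coords=coords,
        eigenvalues=w,
        pop_labels=m.pop_labels,
        n_clamped=n_clamped,
    )


def _contributions(d: PCDecomposition, req: FStatRequest) -> np.ndarray:
    p = [d.coords_of(label) for label in req.pops]
    if req.kind == "f2":
        return (p[0] - p[1]) ** 2
    if req.kind == "f3":
        return (p[0] - p[1]) * (p[0] - p[2])
    return (p[0] - p[1]) * (p[2] - p[3])


def fstat_spectrum(d: PCDecomposition, req: FStatRequest) -> FStatSpectrum:
    """Per-PC contributions of an F-statistic; they sum to the statistic.

    Rotation invariance of the dot product means the F-statistic computed
    on the full PC coordinates equals the one computed on frequencies; for
    F2 each contribution is a square and hence non-negative.
    """
    c = _contributions(d, req)
    return FStatSpectrum(request=req, contributions=c, total=float(c.sum()))


def fstat_truncated(
    d: PCDecomposition, req: FStatRequest, K: int
) -> TruncatedFStat:
    """F-statistic using the first K PCs, with the explicit remainder."""
    if not 0 <= K <= d.k_max:
        raise ValidationError(f"K must be in [0, {d.k_max}], got {K}")
    c = _contributions(d, req)
    approx = float(c[:K].sum())
    total = float(c.sum())
    return TruncatedFStat(
        request=req, K=K, approx=approx, error=total - approx, total=total
    )


def _sqdist(coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        dd = coords - coords[i]
        m[i] = np.einsum("ij,ij->i", dd, dd)
    return m


def f2_frobenius_error(m: F2Matrix, K: int) -> float:
    """Frobenius norm of the rank-K truncation error of the F2 matrix.

    Equals sqrt(sum over all ordered population pairs of the squared
    per-pair truncation errors eps^(K)); zero at K = K_max and
    non-increasing in K. The first K PCs are the *optimal* rank-K
    approximation in this norm (classical MDS / Eckart–Young).
    """
    d = pca_from_f2(m)
    if not 0 <= K <= d.k_max:
        raise ValidationError(f"K must be in [0, {d.k_max}], got {K}")
    err = _sqdist(d.coords) - _sqdist(d.coords[:, :K])
    return float(np.linalg.norm(err, "fro"))


def project_sample(
    d: PCDecomposition,
    new_freqs: np.ndarray,
    missing_mask: np.ndarray | None = None,
) -> ProjectedSample:
    """Project a new frequency vector onto an existing decomposition.

    With complete data the coordinates are (x - mu)/sqrt(S) @ L^T and the
    projection error is the squared norm of the reconstruction residual
    (an F2, in the same units). With missing loci (``missing_mask`` True
    where *missing*, or NaN entries) the coordinates solve an ordinary
    least-squares fit of the observed centred values on the observed
    loading columns, and the error is accumulated over observed loci only.
    """
    if d.loadings is None or d.snp_means is None:
        raise CapabilityError(
            "projection requires a decomposition with loadings and SNP means "
            "(use pca_from_data; the F2 route cannot recover loadings)"
        )
    x = np.asarray(new_freqs, dtype=float)
    s = d.snp_means.shape[0]
    if x.shape != (s,):
        raise ValidationError(f"sample must have {s} loci, got {x.shape}")
    missing = np.isnan(x)
    if missing_mask is not None:
        missing = missing | np.asarray(missing_mask, dtype=bool)
    observed = ~missing
    if not observed.any():
        raise DegeneracyError("all loci missing; nothing to project")
    y = (x - d.snp_means) / np.sqrt(s)
    if observed.all():
        coords = y @ d.loadings.T
        resid = y - coords @ d.loadings
        err = float(resid @ resid)
    else:
        a = d.loadings[:, observed].T  # (#obs, K_max)
        yo = y[observed]
        coords, *_ = np.linalg.lstsq(a, yo, rcond=None)
        resid = yo - a @ coords
        err = float(resid @ resid)
    return ProjectedSample(
        coords=coords, projection_error_f2=err, observed_mask=observed
    )


def f2_with_projected(
    d: PCDecomposition, label: str, sample: ProjectedSample, K: int
) -> ProjectedF2Parts:
    """Three-part split of F2 between a reference population and a sample.

    F2(X_i, X_new) = [first-K PC part] + [truncation remainder]
                     + [projection error]; the split is exact because the
    projection residual is orthogonal to the loading rows. Requires a
    complete-data projection (with missing loci the masked fit is no
    longer orthogonal in the full space).
    """
    if not sample.observed_mask.all():
        raise ValidationError(
            "three-part F2 decomposition requires a complete-data projection"
        )
    if not 0 <= K <= d.k_max:
        raise ValidationError(f"K must be in [0, {d.k_max}], got {K}")
    delta = d.coords_of(label) - sample.coords
    dd = delta * delta
    return ProjectedF2Parts(
        truncated=float(dd[:K].sum()),
        remainder=float(dd[K:].sum()),
        projection_error=sample.projection_error_f2,
    )
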
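"""Geometric diagnostics of F-statistics on PCA plots.

The dot-product view of F-statistics yields simple pictures in PC space:

* **admixture ball** — F3(t; a, b) is negative exactly when t lies inside
  the n-ball whose diameter joins a and b (Pythagorean theorem: F3 = 0 on
  the sphere, < 0 inside, > 0 outside). On a plot showing only some PCs
  the ball projects to a circle; a point inside the projected circle may
  still be outside the ball, but a point *outside* the projected circle in
  any subspace is guaranteed to have F3 > 0.
* **outgroup-F3** — F3(O; U, X_i) is proportional to the signed length of
  the projection of X_i - O onto the axis O -> U, so ranking a panel by
  outgroup-F3 ranks it by position along that axis.
* **F4 as an angle** — F4(a,b;c,d) / sqrt(F2(a,b) F2(c,d)) = cos(phi),
  the correlation between the two drift vectors; orthogonal (tree-like,
  independent) drifts give phi = 90 degrees.
* **F4-ratio** — alpha = F4(R1,R2;X,X1)/F4(R1,R2;X2,X1) is a ratio of
  projected lengths on the reference axis R1 -> R2 and estimates the
  ancestry fraction of X attributable to the X2 side (alpha = 0 at
  X = X1, alpha = 1 at X = X2).
* **residual rotation** — rotate PC space so the reference axis is the
  x-axis; horizontal distances are then proportional to F4 against the
  references, and a PCA of the residual displays what the projection
  ignores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegeneracyError, ValidationError
from .freqs import AlleleFreqMatrix
from .fstats import f2, f3, f4
from .pca import PCDecomposition, _fix_signs

__all__ = [
    "CircleRegion",
    "F3Classification",
    "AngleResult",
    "AdmixtureRatio",
    "OutgroupF3Entry",
    "RotatedCoords",
    "OrthogonalityResult",
    "admixture_circle",
    "classify_f3",
    "outgroup_f3_rank",
    "f4_angle",
    "f4_ratio",
    "residual_rotation",
    "orthogonality_test",
]

#: |F3| below this is "on the sphere"; |F4 denominator| below this
#: (relative to the F2 scale) is a non-informative reference pair.
ON_SPHERE_ATOL = 1e-12
DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class CircleRegion:
    """Projection of the admixture ball onto a PC subspace."""

    source_a: str
    source_b: str
    subspace: tuple[int, ...]
    center: np.ndarray
    radius: float
    full_diameter_f2: float


@dataclass(frozen=True)
class F3Classification:
    """Position of a target relative to the admixture ball of (a, b)."""

    target: str
    f3_value: float
    position: str  # inside_ball | on_sphere | outside_ball
    outside_projected_circle: bool


@dataclass(frozen=True)
class AngleResult:
    """F4 re-expressed as the angle between two difference vectors."""

    cos_phi: float
    phi_degrees: float
    f4_value: float
    K_used: int | str


@dataclass(frozen=True)
class AdmixtureRatio:
    """F4-ratio estimate; ``alpha`` is the fraction from the X2 side."""

    alpha: float
    numerator_f4: float
    denominator_f4: float
    references: tuple[str, str]
    endpoints: tuple[str, str]
    target: str


@dataclass(frozen=True)
class OutgroupF3Entry:
    label: str
    f3: float
    projected_length: float


@dataclass(frozen=True)
class RotatedCoords:
    """Populations in the frame aligned with the reference axis R1 -> R2.

    ``axis_positions`` are signed positions along the unit axis (in
    sqrt-F2 units); differences between them are F4(R2, R1; i, j) divided
    by sqrt(F2(R1, R2)), so ratios of axis distances reproduce F4-ratio
    estimates. ``residual_coords`` are a PCA of the component orthogonal
    to the axis.
    """

    pop_labels: tuple[str, ...]
    axis_positions: np.ndarray
    residual_coords: np.ndarray
    residual_eigenvalues: np.ndarray
    references: tuple[str, str]


@dataclass(frozen=True)
class OrthogonalityResult:
    f4_value: float
    cos_phi: float
    orthogonal: bool


def _subspace_indices(d: PCDecomposition, subspace: tuple[int, ...]) -> np.ndarray:
    if len(subspace) == 0:
        raise ValidationError("subspace must name at least one PC")
    idx = np.asarray(subspace, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= d.k_max:
        raise ValidationError(
            f"subspace PCs must be in 1..{d.k_max}, got {subspace}"
        )
    return idx


def admixture_circle(
    d: PCDecomposition, a: str, b: str, subspace: tuple[int, ...] = (1, 2)
) -> CircleRegion:
    """The projected F3-negative region for sources (a, b) in a subspace.

    The centre is the midpoint of the two sources, the radius half their
    distance, both measured in the named PCs (1-based). The projected
    circle never exceeds the full-space ball: radius^2 <= F2(a, b)/4.
    """
    idx = _subspace_indices(d, subspace)
    pa, pb = d.coords_of(a), d.coords_of(b)
    diff_full = pa - pb
    diff = diff_full[idx]
    return CircleRegion(
        source_a=a,
        source_b=b,
        subspace=tuple(int(k) for k in subspace),
        center=0.5 * (pa[idx] + pb[idx]),
        radius=0.5 * float(np.linalg.norm(diff)),
        full_diameter_f2=float(diff_full @ diff_full),
    )


def classify_f3(
    freqs: AlleleFreqMatrix,
    d: PCDecomposition,
    target: str,
    a: str,
    b: str,
    subspace: tuple[int, ...] = (1, 2),
) -> F3Classification:
    """Classify a target against the admixture ball of sources (a, b).

    The sign of F3 (computed on frequencies) places the target inside, on
    or outside the full ball. ``outside_projected_circle`` tests the
    target's subspace coordinates against the *projection of the full
    ball*: centre at the projected midpoint, radius sqrt(F2(a,b))/2. That
    radius (not the smaller subspace source distance) is what carries the
    guarantee — every F3-negative target lies within it on every
    projection, so a target outside it in any subspace has F3 > 0. The
    test is a strict inequality; boundary points count as not-outside.
    """
    val = f3(freqs, target, a, b)
    if abs(val) < ON_SPHERE_ATOL:
        position = "on_sphere"
    elif val < 0:
        position = "inside_ball"
    else:
        position = "outside_ball"
    region = admixture_circle(d, a, b, subspace)
    idx = _subspace_indices(d, subspace)
    pt = d.coords_of(target)[idx]
    full_radius = 0.5 * np.sqrt(region.full_diameter_f2)
    outside = float(np.linalg.norm(pt - region.center)) > full_radius
    return F3Classification(
        target=target,
        f3_value=val,
        position=position,
        outside_projected_circle=bool(outside),
    )


def outgroup_f3_rank(
    freqs: AlleleFreqMatrix,
    outgroup: str,
    unknown: str,
    panel: list[str],
) -> list[OutgroupF3Entry]:
    """Rank a panel by shared drift with an unknown sample.

    Computes F3(outgroup; unknown, X_i) for each panel member and sorts
    descending; ``projected_length`` = F3 / sqrt(F2(outgroup, unknown)) is
    the signed length of X_i - O projected onto the O -> U axis, so both
    orderings coincide.
    """
    if not panel:
        raise ValidationError("panel must not be empty")
    axis_f2 = f2(freqs, outgroup, unknown)
    if axis_f2 <= 0.0:
        raise DegeneracyError(
            "outgroup and unknown coincide: projection axis has zero length"
        )
    norm = np.sqrt(axis_f2)
    entries = [
        OutgroupF3Entry(
            label=x,
            f3=(v := f3(freqs, outgroup, unknown, x)),
            projected_length=v / norm,
        )
        for x in panel
    ]
    return sorted(entries, key=lambda e: e.f3, reverse=True)


def f4_angle(
    data: AlleleFreqMatrix | PCDecomposition,
    a: str,
    b: str,
    c: str,
    d: str,
    K: int | None = None,
) -> AngleResult:
    """The angle between difference vectors (a - b) and (c - d).

    cos(phi) = F4(a,b;c,d) / sqrt(F2(a,b) * F2(c,d)). On frequencies
    (or with K = None on a decomposition) all three terms use the full
    space; on a decomposition with integer K they use the first K PCs
    only, showing how the apparent angle sharpens as PCs are added.
    """
    if isinstance(data, AlleleFreqMatrix):
        if K is not None:
            raise ValidationError("K applies only to a PC decomposition")
        u = data.row(a) - data.row(b)
        v = data.row(c) - data.row(d)
        scale = data.n_snps
        k_used: int | str = "full"
    else:
        k = data.k_max if K is None else int(K)
        if not 1 <= k <= data.k_max:
            raise ValidationError(f"K must be in [1, {data.k_max}], got {K}")
        u = (data.coords_of(a) - data.coords_of(b))[:k]
        v = (data.coords_of(c) - data.coords_of(d))[:k]
        scale = 1.0
        k_used = "full" if K is None else k
    nu = float(u @ u) / scale
    nv = float(v @ v) / scale
    if nu <= 0.0 or nv <= 0.0:
        raise DegeneracyError("zero-length difference vector; angle undefined")
    f4v = float(u @ v) / scale
    cos_phi = f4v / np.sqrt(nu * nv)
    if abs(cos_phi) > 1.0 + 1e-12:
        raise ValidationError(f"cos(phi) = {cos_phi} outside [-1, 1]")
    phi = float(np.degrees(np.arccos(np.clip(cos_phi, -1.0, 1.0))))
    return AngleResult(
        cos_phi=float(cos_phi), phi_degrees=phi, f4_value=f4v, K_used=k_used
    )


def f4_ratio(
    freqs: AlleleFreqMatrix,
    r1: str,
    r2: str,
    target: str,
    x1: str,
    x2: str,
) -> AdmixtureRatio:
    """Admixture proportion by the F4-ratio.

    alpha = F4(R1,R2; target,X1) / F4(R1,R2; X2,X1): the ratio of the
    projected lengths of (target - X1) and (X2 - X1) on the reference
    axis R1 -> R2. For a drift-free mixture target = (1-w) X1 + w X2 this
    recovers w exactly — alpha is the fraction contributed by the X2 side
    (1 - alpha is the X1 share). A denominator below the degeneracy
    threshold means the references do not separate the endpoints.
    """
    num = f4(freqs, r1, r2, target, x1)
    den = f4(freqs, r1, r2, x2, x1)
    scale = max(f2(freqs, r1, r2), f2(freqs, x1, x2), 1e-300)
    if abs(den) < DEGENERACY_RTOL * scale:
        raise DegeneracyError(
            "F4(R1,R2;X2,X1) is (near) zero: references are uninformative "
            "about the X1-X2 axis"
        )
    return AdmixtureRatio(
        alpha=num / den,
        numerator_f4=num,
        denominator_f4=den,
        references=(r1, r2),
        endpoints=(x1, x2),
        target=target,
    )


def residual_rotation(d: PCDecomposition, r1: str, r2: str) -> RotatedCoords:
    """Rotate PC space so the reference axis R1 -> R2 is the x-axis.

    Each population gets a signed position along the unit axis and
    coordinates in a fresh PCA of the residual (the component orthogonal
    to the axis). Axis-position differences are F4 against the references
    scaled by 1/sqrt(F2(R1,R2)), so relative horizontal distances equal
    F4-ratio admixture estimates; collinearity of a mixture with its
    sources shows up as a small residual.
    """
    axis = d.coords_of(r2) - d.coords_of(r1)
    norm = float(np.linalg.norm(axis))
    scale = max(float(np.abs(d.coords).max()), 1e-300)
    if norm <= 1e-9 * scale:
        raise DegeneracyError("reference populations coincide; no axis")
    u = axis / norm
    t = d.coords @ u
    resid = d.coords - np.outer(t, u)
    resid = resid - resid.mean(axis=0)
    uu, ss, _ = np.linalg.svd(resid, full_matrices=False)
    k = max(d.k_max - 1, 1)
    rc = (uu[:, :k] * ss[:k]).copy()
    _fix_signs(rc, None)
    return RotatedCoords(
        pop_labels=d.pop_labels,
        axis_positions=t,
        residual_coords=rc,
        residual_eigenvalues=ss[:k] ** 2,
        references=(r1, r2),
    )


def orthogonality_test(
    freqs: AlleleFreqMatrix,
    a: str,
    a2: str,
    b: str,
    b2: str,
    tol: float = 0.1,
) -> OrthogonalityResult:
    """Test whether two drift vectors (a - a2) and (b - b2) are orthogonal.

    Returns F4(a, a2; b, b2) plus the correlation cos(phi) and a flag
    |cos(phi)| < tol. Disjoint branches of a tree drift independently and
    should pass; shared drift produces a large correlation. If a pair of
    labels is identical its difference vector is exactly zero: the F4 is 0
    and the pair is reported orthogonal. Distinct labels with coinciding
    frequencies leave the angle undefined and raise a degeneracy error.
    """
    if a == a2 or b == b2:
        return OrthogonalityResult(f4_value=0.0, cos_phi=0.0, orthogonal=True)
    res = f4_angle(freqs, a, a2, b, b2)
    return OrthogonalityResult(
        f4_value=res.f4_value,
        cos_phi=res.cos_phi,
        orthogonal=bool(abs(res.cos_phi) < tol),
    )
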
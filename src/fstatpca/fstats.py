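"""F2, F3 and F4 statistics on population allele frequencies.

With X_i the frequency vector of population i over S SNPs,

    F2(a, b)      = (1/S) * sum_l (x_al - x_bl)^2
    F3(t; a, b)   = (1/S) * sum_l (x_tl - x_al) (x_tl - x_bl)
    F4(a, b; c, d)= (1/S) * sum_l (x_al - x_bl) (x_cl - x_dl)

i.e. F2 is a squared Euclidean distance and F3/F4 are dot products of
difference vectors, all scaled by 1/S. F3 and F4 are linear combinations
of pairwise F2 values:

    2 F3(t; a, b)    = F2(t, a) + F2(t, b) - F2(a, b)
    2 F4(a, b; c, d) = F2(a, d) + F2(b, c) - F2(a, c) - F2(b, d)

These are the plug-in statistics on given frequencies; no finite-sample
bias correction is applied. Bias-corrected estimates produced by external
tools can be supplied as an :class:`F2Matrix` with ``source="external"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import LabelError, ValidationError
from .freqs import AlleleFreqMatrix

__all__ = ["F2Matrix", "f2", "f3", "f4", "pairwise_f2", "f3_from_f2", "f4_from_f2"]

#: relative tolerance (to the largest entry) for symmetry / diagonal checks
SYMMETRY_RTOL = 1e-12


@dataclass
class F2Matrix:
    """Symmetric n x n matrix of pairwise F2 values with zero diagonal.

    ``source`` records provenance: ``"computed"`` means plug-in values from
    frequencies (necessarily >= 0, a squared Euclidean distance matrix);
    ``"external"`` marks estimates read from a file, where sampling noise
    may make some entries slightly negative or the matrix non-Euclidean.
    """

    values: np.ndarray
    pop_labels: tuple[str, ...]
    source: str = "computed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("F2 matrix must be square")
        n = self.values.shape[0]
        self.pop_labels = tuple(str(p) for p in self.pop_labels)
        if len(self.pop_labels) != n or len(set(self.pop_labels)) != n:
            raise ValidationError("need n unique population labels")
        if self.source not in ("computed", "external"):
            raise ValidationError(f"unknown F2 source: {self.source!r}")
        scale = max(float(np.abs(self.values).max()), 1e-300)
        if np.abs(self.values - self.values.T).max() > SYMMETRY_RTOL * scale:
            raise ValidationError("F2 matrix is not symmetric")
        if np.abs(np.diag(self.values)).max() > SYMMETRY_RTOL * scale:
            raise ValidationError("F2 matrix diagonal must be zero")
        if self.source == "computed" and self.values.min() < 0.0:
            raise ValidationError("computed F2 matrix must be non-negative")
        self._index = {p: i for i, p in enumerate(self.pop_labels)}

    @property
    def n_pops(self) -> int:
        return self.values.shape[0]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise LabelError(f"unknown population label: {label!r}") from None


def f2(freqs: AlleleFreqMatrix, a: str, b: str) -> float:
    """Mean squared frequency difference between populations a and b."""
    d = freqs.row(a) - freqs.row(b)
    return float(d @ d) / freqs.n_snps


def f3(freqs: AlleleFreqMatrix, target: str, a: str, b: str) -> float:
    """Dot product of (target - a) and (target - b), scaled by 1/S.

    Negative values indicate the target lies "between" a and b (inside the
    ball with diameter ab) and are a classic signal of admixture.
    """
    xt = freqs.row(target)
    da = xt - freqs.row(a)
    db = xt - freqs.row(b)
    return float(da @ db) / freqs.n_snps


def f4(freqs: AlleleFreqMatrix, a: str, b: str, c: str, d: str) -> float:
    """Dot product of (a - b) and (c - d), scaled by 1/S ("treeness" test)."""
    dab = freqs.row(a) - freqs.row(b)
    dcd = freqs.row(c) - freqs.row(d)
    return float(dab @ dcd) / freqs.n_snps


def pairwise_f2(freqs: AlleleFreqMatrix) -> F2Matrix:
    """All pairwise F2 values, the sufficient statistic for the PCA link."""
    x = freqs.values
    n, s = x.shape
    m = np.zeros((n, n))
    # row-by-row squared distances: bit-identical to looped f2() calls
    for i in range(n):
        d = x - x[i]
        m[i] = np.einsum("ij,ij->i", d, d) / s
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return F2Matrix(m, freqs.pop_labels, source="computed")


def f3_from_f2(m: F2Matrix, target: str, a: str, b: str) -> float:
    """F3 via the exact identity 2*F3 = F2(t,a) + F2(t,b) - F2(a,b)."""
    t, i, j = m.index(target), m.index(a), m.index(b)
    v = m.values
    return 0.5 * (v[t, i] + v[t, j] - v[i, j])


def f4_from_f2(m: F2Matrix, a: str, b: str, c: str, d: str) -> float:
    """F4 via 2*F4 = F2(a,d) + F2(b,c) - F2(a,c) - F2(b,d).

    Expanding <a-b, c-d> in squared norms: the squared-norm terms cancel
    and the cross terms leave exactly this combination.
    """
    i, j, k, l = m.index(a), m.index(b), m.index(c), m.index(d)
    v = m.values
    return 0.5 * (v[i, l] + v[j, k] - v[i, k] - v[j, l])
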
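"""Population allele-frequency matrices.

A population is represented solely by its vector of allele frequencies at S
biallelic SNPs, i.e. a point in the S-dimensional allele-frequency space
[0,1]^S. All F-statistics and the PCA link operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import LabelError, ValidationError

__all__ = ["AlleleFreqMatrix", "FStatRequest"]

_ARITY = {"f2": 2, "f3": 3, "f4": 4}


@dataclass
class AlleleFreqMatrix:
    """n populations x S SNPs of allele frequencies in [0, 1].

    Parameters
    ----------
    values
        Array of shape (n, S); every entry must be finite and in [0, 1].
        Missing data is not representable at this layer: incomplete SNPs
        must be dropped (or imputed) upstream.
    pop_labels
        n unique population names (row labels).
    snp_ids
        S unique SNP identifiers (column labels); autogenerated
        ``snp0..snp{S-1}`` when omitted.
    """

    values: np.ndarray
    pop_labels: tuple[str, ...]
    snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("frequency values must be a 2-D array")
        n, s = self.values.shape
        if n < 1 or s < 1:
            raise ValidationError("need at least one population and one SNP")
        self.pop_labels = tuple(str(p) for p in self.pop_labels)
        if len(self.pop_labels) != n:
            raise ValidationError(
                f"{len(self.pop_labels)} labels for {n} populations"
            )
        if len(set(self.pop_labels)) != n:
            raise ValidationError("population labels must be unique")
        if not self.snp_ids:
            self.snp_ids = tuple(f"snp{i}" for i in range(s))
        else:
            self.snp_ids = tuple(str(x) for x in self.snp_ids)
        if len(self.snp_ids) != s:
            raise ValidationError(f"{len(self.snp_ids)} SNP ids for {s} SNPs")
        if len(set(self.snp_ids)) != s:
            raise ValidationError("SNP ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("allele frequencies must be finite")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValidationError("allele frequencies must lie in [0, 1]")
        self._index = {p: i for i, p in enumerate(self.pop_labels)}

    @property
    def n_pops(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise LabelError(f"unknown population label: {label!r}") from None

    def row(self, label: str) -> np.ndarray:
        """Frequency vector X_i for one population (view, do not mutate)."""
        return self.values[self.index(label)]


@dataclass(frozen=True)
class FStatRequest:
    """Selector for one F-statistic: its kind and ordered population tuple.

    Order matters: F3's first population is the target, F4 pairs are
    (a, b; c, d). Repeats are allowed (e.g. F4(a,b;a,b) = F2(a,b)).
    """

    kind: str
    pops: tuple[str, ...]

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "pops", tuple(str(p) for p in self.pops))
        if kind not in _ARITY:
            raise ValidationError(f"unknown F-statistic kind: {self.kind!r}")
        if len(self.pops) != _ARITY[kind]:
            raise ValidationError(
                f"{kind} needs {_ARITY[kind]} populations, got {len(self.pops)}"
            )
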
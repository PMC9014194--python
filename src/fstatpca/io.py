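"""Readers and writers for the plain-text formats the tool touches.

Frequency tables and F2 matrices are TSV with a header row; PC
coordinates and spectra are TSV with ``#``-prefixed metadata comments.
EIGENSTRAT geno/ind/snp triples are aggregated to population allele
frequencies. All round-trips are lossless at 12 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import ParseError, ValidationError
from .freqs import AlleleFreqMatrix
from .fstats import F2Matrix
from .pca import FStatSpectrum, PCDecomposition

__all__ = [
    "read_freq_table",
    "write_freq_table",
    "freqs_from_eigenstrat",
    "read_f2_matrix",
    "write_f2_matrix",
    "write_pc_coords",
    "write_spectrum",
    "write_pca_dir",
    "read_pca_dir",
]

_FMT = "%.12g"

#: relative asymmetry beyond this in an F2 file is an error, below it the
#: matrix is silently symmetrised (absorbs decimal round-trips)
F2_FILE_RTOL = 1e-8


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: not a number: {token!r}"
        ) from None


def read_freq_table(path: str | Path) -> AlleleFreqMatrix:
    """Read a TSV of population allele frequencies.

    Header row: ``population`` followed by SNP ids; one row per
    population with decimal frequencies in [0, 1]. Errors name the
    offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "population":
        raise ParseError(
            f"{path}:1: header must be 'population' followed by SNP ids"
        )
    snp_ids = tuple(header[1:])
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        if fields[0] in labels:
            raise ParseError(
                f"{path}:{lineno}: duplicate population {fields[0]!r}"
            )
        vals = [_parse_float(t, str(path), lineno) for t in fields[1:]]
        bad = [v for v in vals if not (0.0 <= v <= 1.0)]
        if bad:
            raise ParseError(
                f"{path}:{lineno}: frequency {bad[0]} outside [0, 1]"
            )
        labels.append(fields[0])
        rows.append(vals)
    if not rows:
        raise ParseError(f"{path}:1: no population rows")
    return AlleleFreqMatrix(np.array(rows), tuple(labels), snp_ids)


def write_freq_table(freqs: AlleleFreqMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("population\t" + "\t".join(freqs.snp_ids) + "\n")
        for label, row in zip(freqs.pop_labels, freqs.values):
            fh.write(label + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def freqs_from_eigenstrat(
    geno_path: str | Path,
    ind_path: str | Path,
    snp_path: str | Path,
    drop_incomplete: bool = True,
) -> AlleleFreqMatrix:
    """Aggregate an EIGENSTRAT geno/ind/snp triple to population frequencies.

    Genotypes are 0/1/2 counts of the reference allele (9 = missing); a
    population's frequency is the mean genotype over its non-missing
    individuals divided by 2. With ``drop_incomplete`` (default, matching
    the usual practice of excluding SNPs missing in any population) every
    SNP with zero observations in *any* population is dropped; without it
    such a SNP raises an error, since frequencies cannot contain holes.
    """
    geno_path, ind_path, snp_path = map(Path, (geno_path, ind_path, snp_path))
    ind_pops: list[str] = []
    for lineno, line in enumerate(ind_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ParseError(
                f"{ind_path}:{lineno}: expected 3 fields, got {len(fields)}"
            )
        ind_pops.append(fields[2])
    snp_ids: list[str] = []
    for lineno, line in enumerate(snp_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(
                f"{snp_path}:{lineno}: expected >= 4 fields, got {len(fields)}"
            )
        snp_ids.append(fields[0])
    geno_lines = [
        ln for ln in geno_path.read_text().splitlines() if ln.strip()
    ]
    if len(geno_lines) != len(snp_ids):
        raise ParseError(
            f"{geno_path}: {len(geno_lines)} genotype lines for "
            f"{len(snp_ids)} SNPs"
        )
    pops = tuple(dict.fromkeys(ind_pops))  # first-appearance order
    pop_cols = {p: [i for i, q in enumerate(ind_pops) if q == p] for p in pops}
    n_ind = len(ind_pops)
    freq_rows: list[list[float]] = []
    keep: list[bool] = []
    for lineno, line in enumerate(geno_lines, start=1):
        if len(line) != n_ind:
            raise ParseError(
                f"{geno_path}:{lineno}: {len(line)} genotypes for "
                f"{n_ind} individuals"
            )
        try:
            g = np.array([int(ch) for ch in line])
        except ValueError:
            raise ParseError(
                f"{geno_path}:{lineno}: non-digit genotype character"
            ) from None
        if np.any((g > 2) & (g != 9)):
            raise ParseError(
                f"{geno_path}:{lineno}: genotypes must be 0/1/2/9"
            )
        row: list[float] = []
        complete = True
        for p in pops:
            sub = g[pop_cols[p]]
            obs = sub[sub != 9]
            if obs.size == 0:
                complete = False
                row.append(np.nan)
            else:
                row.append(float(obs.mean()) / 2.0)
        keep.append(complete)
        if not complete and not drop_incomplete:
            raise ParseError(
                f"{geno_path}:{lineno}: SNP has no data in some population "
                "(rerun with drop_incomplete=True to exclude such SNPs)"
            )
        freq_rows.append(row)
    kept = [i for i, k in enumerate(keep) if k]
    if not kept:
        raise ValidationError("no SNP has data in every population")
    values = np.array([freq_rows[i] for i in kept]).T  # pops x SNPs
    return AlleleFreqMatrix(values, pops, tuple(snp_ids[i] for i in kept))


def read_f2_matrix(path: str | Path) -> F2Matrix:
    """Read a square labelled TSV of pairwise F2 values.

    Small asymmetries (file round-off) are averaged away; asymmetry
    beyond ``F2_FILE_RTOL`` relative to the largest entry is an error, as
    is a non-square table or mismatched row/column labels. The result has
    ``source="external"`` (small negative entries permitted).
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    header = lines[0].split("\t")
    if header[0] != "population":
        raise ParseError(f"{path}:1: header must start with 'population'")
    col_labels = header[1:]
    n = len(col_labels)
    if len(lines) - 1 != n:
        raise ParseError(
            f"{path}: matrix is not square ({len(lines) - 1} rows, "
            f"{n} columns)"
        )
    rows = []
    row_labels = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {n + 1} fields, got {len(fields)}"
            )
        row_labels.append(fields[0])
        rows.append([_parse_float(t, str(path), lineno) for t in fields[1:]])
    if row_labels != col_labels:
        raise ParseError(f"{path}: row labels do not match column labels")
    m = np.array(rows)
    scale = max(float(np.abs(m).max()), 1e-300)
    if np.abs(m - m.T).max() > F2_FILE_RTOL * scale:
        raise ParseError(f"{path}: matrix is asymmetric beyond tolerance")
    if np.abs(np.diag(m)).max() > F2_FILE_RTOL * scale:
        raise ParseError(f"{path}: matrix diagonal is not zero")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return F2Matrix(m, tuple(row_labels), source="external")


def write_f2_matrix(m: F2Matrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("population\t" + "\t".join(m.pop_labels) + "\n")
        for label, row in zip(m.pop_labels, m.values):
            fh.write(label + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def write_pc_coords(d: PCDecomposition, path: str | Path) -> None:
    """PC coordinates as TSV; eigenvalues and clamp count in '#' comments."""
    with open(path, "w") as fh:
        fh.write(
            "# eigenvalues\t"
            + "\t".join(_FMT % v for v in d.eigenvalues)
            + "\n"
        )
        fh.write(f"# n_clamped\t{d.n_clamped}\n")
        fh.write(
            "population\t"
            + "\t".join(f"PC{k + 1}" for k in range(d.k_max))
            + "\n"
        )
        for label, row in zip(d.pop_labels, d.coords):
            fh.write(label + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def write_spectrum(s: FStatSpectrum, path: str | Path) -> None:
    """Per-PC contributions as TSV of (PC index, contribution)."""
    with open(path, "w") as fh:
        fh.write(f"# statistic\t{s.request.kind}({','.join(s.request.pops)})\n")
        fh.write(f"# total\t{_FMT % s.total}\n")
        fh.write("pc\tcontribution\n")
        for k, c in enumerate(s.contributions, start=1):
            fh.write(f"{k}\t{_FMT % c}\n")


def write_pca_dir(d: PCDecomposition, outdir: str | Path) -> None:
    """Persist a full decomposition (coords, loadings, SNP means) to a
    directory so samples can be projected in a later invocation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pc_coords(d, outdir / "coords.tsv")
    if d.loadings is not None and d.snp_means is not None:
        np.savetxt(outdir / "loadings.tsv", d.loadings, fmt=_FMT, delimiter="\t")
        np.savetxt(outdir / "snp_means.tsv", d.snp_means, fmt=_FMT, delimiter="\t")


def read_pca_dir(outdir: str | Path) -> PCDecomposition:
    outdir = Path(outdir)
    lines = (outdir / "coords.tsv").read_text().splitlines()
    eigenvalues = None
    n_clamped = 0
    data_lines = []
    for ln in lines:
        if ln.startswith("# eigenvalues\t"):
            eigenvalues = np.array([float(t) for t in ln.split("\t")[1:]])
        elif ln.startswith("# n_clamped\t"):
            n_clamped = int(ln.split("\t")[1])
        elif ln.startswith("#") or not ln.strip():
            continue
        else:
            data_lines.append(ln)
    if eigenvalues is None:
        raise ParseError(f"{outdir / 'coords.tsv'}: missing eigenvalue header")
    labels = []
    coords = []
    for ln in data_lines[1:]:  # skip the column-header line
        fields = ln.split("\t")
        labels.append(fields[0])
        coords.append([float(t) for t in fields[1:]])
    loadings = snp_means = None
    if (outdir / "loadings.tsv").exists():
        loadings = np.atleast_2d(
            np.loadtxt(outdir / "loadings.tsv", delimiter="\t")
        )
        snp_means = np.atleast_1d(
            np.loadtxt(outdir / "snp_means.tsv", delimiter="\t")
        )
    return PCDecomposition(
        coords=np.array(coords),
        eigenvalues=eigenvalues,
        pop_labels=tuple(labels),
        loadings=loadings,
        snp_means=snp_means,
        n_clamped=n_clamped,
    )
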
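"""Optional matplotlib figures for the geometric diagnostics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geometry import CircleRegion, RotatedCoords
from .pca import FStatSpectrum, PCDecomposition

__all__ = ["biplot_with_circle", "spectrum_bars", "rotation_scatter"]


def biplot_with_circle(
    d: PCDecomposition,
    path: str | Path,
    circle: CircleRegion | None = None,
    pcs: tuple[int, int] = (1, 2),
) -> None:
    """PC biplot with an optional admixture-circle overlay.

    The grey disc marks where a target of the circle's two sources could
    have a negative F3 as judged from these two PCs alone; the dashed
    circle shows the (always larger) bound from the full-space F2.
    """
    i, j = pcs[0] - 1, pcs[1] - 1
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(d.coords[:, i], d.coords[:, j], s=18, zorder=3)
    for label, row in zip(d.pop_labels, d.coords):
        ax.annotate(label, (row[i], row[j]), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    if circle is not None and tuple(circle.subspace) == tuple(pcs):
        ax.add_patch(
            plt.Circle(circle.center, circle.radius, color="0.55", alpha=0.4,
                       zorder=1)
        )
        full_radius = 0.5 * np.sqrt(circle.full_diameter_f2)
        ax.add_patch(
            plt.Circle(circle.center, full_radius, fill=False, ls="--",
                       color="0.4", zorder=2)
        )
    ax.set_xlabel(f"PC{pcs[0]}")
    ax.set_ylabel(f"PC{pcs[1]}")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def spectrum_bars(s: FStatSpectrum, path: str | Path, max_pcs: int = 10) -> None:
    """Bar chart of the leading per-PC contributions to one F-statistic."""
    k = min(max_pcs, len(s.contributions))
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(np.arange(1, k + 1), s.contributions[:k])
    ax.axhline(0, color="0.3", lw=0.8)
    ax.set_xlabel("PC")
    ax.set_ylabel("contribution")
    name = f"{s.request.kind}({', '.join(s.request.pops)})"
    ax.set_title(f"{name} = {s.total:.4g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def rotation_scatter(rot: RotatedCoords, path: str | Path) -> None:
    """Populations along the reference axis vs. first residual PC."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(rot.axis_positions, rot.residual_coords[:, 0], s=18)
    for label, x, y in zip(
        rot.pop_labels, rot.axis_positions, rot.residual_coords[:, 0]
    ):
        ax.annotate(label, (x, y), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    r1, r2 = rot.references
    ax.set_xlabel(f"position along {r1} → {r2} axis")
    ax.set_ylabel("residual PC1")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
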
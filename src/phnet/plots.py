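"""Optional figures: Betti-0 curve, barcode, dendrogram and snapshots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .connectivity import DistanceMatrix
from .persistence import PersistenceResult, snapshot_graph

__all__ = ["plot_pathway"]


def plot_pathway(
    res: PersistenceResult,
    dist: DistanceMatrix,
    out_dir: Path,
    lambdas: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25),
) -> list[Path]:
    """Write Betti-0 curve, barcode and snapshot figures for one pathway."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # Betti-0 step curve
    bp = np.concatenate([[0.0], res.betti.breakpoints, [1.0]])
    counts = np.concatenate([res.betti.counts, [res.betti.counts[-1]]])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.step(bp, counts, where="post")
    ax.set_xlabel("filtration λ")
    ax.set_ylabel("β₀ (connected components)")
    ax.set_title(f"SIP AUC = {res.sip_auc:.3f}")
    fig.tight_layout()
    p = out_dir / "betti0_curve.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # barcode
    fig, ax = plt.subplots(figsize=(4, 3))
    for k, (b, d) in enumerate(sorted(res.barcode.bars, key=lambda bd: bd[1])):
        ax.hlines(k, b, d, lw=2)
    ax.set_xlabel("filtration λ")
    ax.set_ylabel("component bar")
    fig.tight_layout()
    p = out_dir / "barcode.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # snapshot graphs on a circular layout
    n = dist.n_rois
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    fig, axes = plt.subplots(1, len(lambdas), figsize=(2.2 * len(lambdas), 2.4))
    for ax, lam in zip(np.atleast_1d(axes), lambdas):
        snap = snapshot_graph(dist, lam)
        for i, j, _ in snap.edges:
            ax.plot(xy[[i, j], 0], xy[[i, j], 1], color="0.6", lw=0.8, zorder=1)
        ax.scatter(xy[:, 0], xy[:, 1], c=snap.component_labels, cmap="tab20",
                   s=30, zorder=2)
        ax.set_title(f"λ={lam:.2f}\nβ₀={snap.n_components}", fontsize=8)
        ax.set_axis_off()
    fig.tight_layout()
    p = out_dir / "snapshots.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
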
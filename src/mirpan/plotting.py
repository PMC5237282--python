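"""Rendering of the 3D treatment-space map."""

from __future__ import annotations

import numpy as np

from .treatments import TreatmentCatalog

__all__ = ["plot_treatment_map"]


def plot_treatment_map(
    catalog: TreatmentCatalog,
    path,
    counts: dict[str, int] | None = None,
) -> None:
    """Scatter the Cox-scaled cluster coordinates to an image file.

    Marker color encodes treatment prevalence (cluster member count or the
    supplied per-treatment counts) on a jet colormap, warm colors for the
    most prevalent treatments.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = catalog.cluster_ids
    coords = np.array([catalog.coordinates[c] for c in clusters])
    counts = counts or {}
    sizes = np.array(
        [
            sum(counts.get(t, 1) for t, c in catalog.clusters.items() if c == cluster)
            for cluster in clusters
        ],
        dtype=float,
    )
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(111, projection="3d")
    sc = ax.scatter(
        coords[:, 0], coords[:, 1], coords[:, 2],
        c=-sizes, cmap="jet", s=30 + 10 * sizes,
    )
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    ax.set_title("Treatment space (Cox scaling)")
    fig.colorbar(sc, label="prevalence (warm = more prevalent)", shrink=0.6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
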
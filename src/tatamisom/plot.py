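"""Basic grid heat plot of a Tatami map."""

from __future__ import annotations

import numpy as np

from .tatami import TatamiMap


def plot_tatami(tmap: TatamiMap, n_rows: int, n_cols: int, ax=None, cmap=None, annotate_ids=False):
    """Render one Tatami map as a rows x cols heat grid; returns the Axes.

    Empty (NaN) transcription nodes are left blank.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(n_cols / 2.5, n_rows / 2.5))
    values = tmap.values.reindex(range(1, n_rows * n_cols + 1)).to_numpy(dtype=float)
    img = values.reshape(n_rows, n_cols)
    default = "viridis" if tmap.kind == "transcription" else "magma"
    mesh = ax.imshow(img, cmap=cmap or default, aspect="equal")
    ax.figure.colorbar(mesh, ax=ax, shrink=0.8, label=tmap.kind)
    if annotate_ids:
        for node in range(1, n_rows * n_cols + 1):
            r, c = (node - 1) // n_cols, (node - 1) % n_cols
            if np.isfinite(img[r, c]):
                ax.text(c, r, str(node), ha="center", va="center", fontsize=4)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
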
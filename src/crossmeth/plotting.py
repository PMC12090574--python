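"""Optional plotting helpers (thin stubs over matplotlib).

Only basic heatmaps are provided; hierarchical clustering with optimal leaf
ordering of publication figures is out of scope.
"""

from __future__ import annotations

from .data import CombinationMeanMatrix


def combination_heatmap(combos: CombinationMeanMatrix, ax=None, **imshow_kwargs):
    """Rows = combination mean samples, columns = probes, values 0..1."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(combos.values, aspect="auto", vmin=0.0, vmax=1.0,
                   **imshow_kwargs)
    ax.set_yticks(range(len(combos.keys)))
    ax.set_yticklabels([f"{s}/{t}" for s, t in combos.keys], fontsize=6)
    ax.set_xlabel("probe")
    return im
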
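"""Plots mirroring the study's summary figures (matplotlib, optional)."""

from __future__ import annotations

import numpy as np


def sv_vs_gc(results, k_highlight: int = 10, ax=None):
    """Scatter of sequence variability against GC content per region,
    highlighting the top-k hotspots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    ordered = sorted(results, key=lambda r: -r.sv)
    sv = np.array([r.sv for r in ordered])
    gc = np.array([100 * r.gc for r in ordered])
    ax.scatter(gc[k_highlight:], sv[k_highlight:], s=14, c="grey", alpha=0.7)
    ax.scatter(gc[:k_highlight], sv[:k_highlight], s=26, c="crimson")
    for r in ordered[:k_highlight]:
        ax.annotate(r.name, (100 * r.gc, r.sv), fontsize=6, alpha=0.8)
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("sequence variability SV (%)")
    return ax


def rscu_heatmap(usage, ax=None):
    """Heatmap of RSCU values (codons x taxa)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 10))
    taxa = usage.taxa
    table = usage.table
    sense = table[table["aa"] != "*"]
    values = sense[[f"rscu_{t}" for t in taxa]].to_numpy(dtype=float)
    im = ax.imshow(values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(taxa)), taxa, rotation=90, fontsize=6)
    ax.set_yticks(range(len(sense)), sense["codon"], fontsize=4)
    ax.figure.colorbar(im, ax=ax, label="RSCU")
    return ax
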
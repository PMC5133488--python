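"""Manhattan-style plot of region-level permutation p-values."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(results_table: pd.DataFrame, path, title: str = "Region scan") -> None:
    """Plot −log10 of the three p-value series against region order.

    Regions with NA p-values (e.g. no rare variants) are omitted.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_table.dropna(subset=["global_p_IA", "local_p_IA", "p_I1"]).reset_index()
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(10, 4))
    for col, marker in (("global_p_IA", "o"), ("local_p_IA", "s"), ("p_I1", "^")):
        ax.scatter(x, -np.log10(df[col]), s=14, marker=marker, label=col, alpha=0.7)
    # shade alternating chromosomes for orientation
    chroms = df["chromosome"].tolist()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            if (df["chromosome"].drop_duplicates().tolist().index(chroms[start])) % 2:
                ax.axvspan(start - 0.5, i - 0.5, color="0.92", zorder=0)
            start = i
    ax.set_xlabel("region (genome order)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
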
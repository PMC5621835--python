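"""Optional figure-style outputs (scatter with fit, fold-change histogram,
tissue r² heatmap)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def regression_scatter(log_before, log_after, fit, path: str | Path,
                       xlabel: str = "log10(RPM+1), before",
                       ylabel: str = "log10(RPM+1), after") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(log_before, log_after, s=8, alpha=0.5)
    xs = np.linspace(0, max(max(log_before, default=1), 1), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-",
            label=f"r²={fit.r2:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fold_change_histogram(profile: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(profile["log10_fold_change"], bins=30)
    ax.set_xlabel("log10 fold change (RPM+1)")
    ax.set_ylabel("alleles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="r²")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
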
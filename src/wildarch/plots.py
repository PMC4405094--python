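"""Plot hooks: Manhattan, Q-Q, regional-h2 and haplotype-sharing figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan", "qq_plot", "regional_h2_plot", "hs_barplot"]


def manhattan(scan: pd.DataFrame, threshold: float | None = None, ax=None):
    """-log10 P against genome position, coloured by chromosome."""
    ax = ax or plt.subplots(figsize=(9, 3))[1]
    offset = 0
    ticks = []
    for i, (chrom, sub) in enumerate(scan.groupby("chrom", sort=False)):
        x = sub["bp"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["p"]), s=6, color=f"C{i % 2}")
        ticks.append((offset + sub["bp"].max() / 2, str(chrom)))
        offset += sub["bp"].max()
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="k", lw=0.8)
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([l for _, l in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    return ax


def qq_plot(pvalues: np.ndarray, ax=None):
    """Observed vs expected -log10 P under the uniform null."""
    ax = ax or plt.subplots(figsize=(3.2, 3.2))[1]
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    ax.scatter(exp, -np.log10(p)[::-1] if False else -np.log10(p[::-1])[::-1], s=5)
    ax.plot([0, exp.max()], [0, exp.max()], "k-", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} P$")
    ax.set_ylabel(r"observed $-\log_{10} P$")
    return ax


def regional_h2_plot(table: pd.DataFrame, threshold: float | None = None, ax=None):
    """Per-region variance share along the genome with significance stars."""
    ax = ax or plt.subplots(figsize=(9, 3))[1]
    x = np.arange(len(table))
    ax.bar(x, table["h2_unit"], color="C0")
    if threshold is not None and "p" in table:
        sig = table["p"] < threshold
        ax.scatter(x[sig], table.loc[sig, "h2_unit"] + 0.005, marker="*", color="C3")
    ax.set_xlabel("region (genome order)")
    ax.set_ylabel(r"$h^2_{\mathrm{region}}$")
    return ax


def hs_barplot(hs_table: pd.DataFrame, ax=None):
    """Mean +- SD sharing length per breed for one core haplotype."""
    ax = ax or plt.subplots(figsize=(6, 3))[1]
    sub = hs_table.dropna(subset=["mean_bp"])
    ax.bar(sub["breed"], sub["mean_bp"] / 1e6, yerr=sub["sd_bp"] / 1e6, color="C0")
    ax.set_ylabel("haplotype sharing (Mb)")
    ax.tick_params(axis="x", rotation=45)
    return ax
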
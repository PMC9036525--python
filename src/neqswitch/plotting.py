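"""Matplotlib figures: quasi-time-series, work densities, PCA biplots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "plot_quasi_time_series",
    "plot_work_density",
    "plot_pca",
    "plot_delta_vs_length",
]


def plot_quasi_time_series(qts, path):
    """Work values vs global switch index, block separators, mean and -k sigma lines."""
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(qts.global_indices, qts.works, ".", ms=3, color="0.3")
    out = np.isin(qts.global_indices, qts.outlier_indices)
    if out.any():
        ax.plot(qts.global_indices[out], qts.works[out], "o", mfc="none",
                mec="green", ms=9, label="outliers")
    ax.axhline(qts.mean, color="green", lw=1, label=r"$\bar{W}$")
    ax.axhline(qts.mean - qts.k * qts.sigma, color="red", lw=1,
               label=rf"$\bar{{W}} - {qts.k:g}\sigma$")
    for b in qts.block_boundaries[1:]:
        ax.axvline(b - 0.5, color="0.8", lw=0.8)
    ax.set_xlabel("switch index")
    ax.set_ylabel("W [kcal/mol]")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_work_density(density_fw, density_bw_neg=None, path=None, ax=None):
    """Kernel densities of forward and (negated) backward work values."""
    own = ax is None
    if own:
        fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(density_fw["work_kcal_mol"], density_fw["density"], label="forward")
    if density_bw_neg is not None:
        ax.plot(density_bw_neg["work_kcal_mol"], density_bw_neg["density"],
                label="-backward")
    ax.set_xlabel("W [kcal/mol]")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    if own and path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def plot_pca(pca, features, path, arrow_scale=None):
    """PC1-vs-PC2 score plot with loading arrows; flagged switches marked.

    Arrows use a correlation-biplot convention (loadings scaled by singular
    values, then rescaled to the score cloud) -- cosmetic only.
    """
    fig, ax = plt.subplots(figsize=(5.5, 5))
    s = pca.scores
    flagged = np.isin(pca.row_labels, pca.flagged)
    ax.plot(s[~flagged, 0], s[~flagged, 1], "o", color="green", ms=4, alpha=0.6)
    if flagged.any():
        ax.plot(s[flagged, 0], s[flagged, 1], "^", color="red", ms=8)
        for i in np.flatnonzero(flagged):
            ax.annotate(str(pca.row_labels[i]), (s[i, 0], s[i, 1]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    arrows = pca.loadings[:, :2] * pca.singular_values[:2]
    if arrow_scale is None:
        span = max(np.abs(s[:, :2]).max(), 1e-12)
        arrow_scale = 0.8 * span / max(np.abs(arrows).max(), 1e-12)
    for i, name in enumerate(pca.feature_names):
        dx, dy = arrows[i] * arrow_scale
        ax.annotate("", xy=(dx, dy), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="0.2"))
        ax.annotate(name, (dx, dy), fontsize=8, color="0.2")
    ev = pca.explained_fraction
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)" if ev.size > 1 else "PC2")
    title = "scaled PCA" if pca.scaled else "unscaled PCA"
    if pca.flag_criterion:
        title += f" — flagged by {pca.flag_criterion}"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_delta_vs_length(cells, config, path):
    """delta_delta_a (JAR - CRO) versus switching length, with uncertainties."""
    lengths = {p.name: p.n_switch for p in config.protocols}
    fig, ax = plt.subplots(figsize=(5, 3.2))
    xs, ys, es = [], [], []
    for c in cells:
        if c.protocol in lengths:
            xs.append(lengths[c.protocol])
            ys.append(c.delta_delta_a)
            es.append(np.hypot(c.jar_uncertainty, c.cro_uncertainty))
    order = np.argsort(xs)
    xs, ys, es = np.array(xs)[order], np.array(ys)[order], np.array(es)[order]
    ax.errorbar(xs, ys, yerr=es, fmt="o-", capsize=3)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("switching length [steps]")
    ax.set_ylabel(r"$\delta\Delta A$ [kcal/mol]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
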
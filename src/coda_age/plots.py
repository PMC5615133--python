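"""Figure rendering from the pipeline's written TSVs (never in-memory state).

Keeping plots downstream of the TSV artifacts makes every figure
reproducible post hoc from the report bundle alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["biplot", "effect_strips", "cluster_trends", "render_all"]

#: 75% normal-theory coverage radius for a 2-D covariance ellipse.
ELLIPSE_SCALE = float(np.sqrt(chi2.ppf(0.75, df=2)))


def _ellipse(ax, xy: np.ndarray, color) -> None:
    """Draw the 75% data ellipse of a 2-column point cloud."""
    if len(xy) < 3:
        return
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0, None)
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    pts = mean[:, None] + ELLIPSE_SCALE * vecs @ (np.sqrt(vals)[:, None] * circle)
    ax.plot(pts[0], pts[1], color=color, lw=1.2)


def biplot(out_dir: Path, prefix: str, group_column: str = "group") -> Path | None:
    scores_path = out_dir / f"{prefix}_scores.tsv"
    if not scores_path.exists():
        return None
    scores = pd.read_csv(scores_path, sep="\t", comment="#", index_col=0)
    loadings = pd.read_csv(
        out_dir / f"{prefix}_loadings.tsv", sep="\t", comment="#", index_col=0
    )
    var = pd.read_csv(out_dir / f"{prefix}_variance.tsv", sep="\t")
    groups = pd.read_csv(out_dir / "sample_groups.tsv", sep="\t", index_col=0)["group"]

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    cmap = plt.get_cmap("tab10")
    for i, (g, ids) in enumerate(groups.groupby(groups).groups.items()):
        pts = scores.loc[ids, ["PC1", "PC2"]].to_numpy()
        color = cmap(i % 10)
        axes[0].scatter(pts[:, 0], pts[:, 1], s=8, color=color, label=str(g), alpha=0.7)
        _ellipse(axes[0], pts, color)
    axes[0].legend(fontsize=7)
    axes[1].scatter(loadings["PC1"], loadings["PC2"], s=8, color="gray")
    for ax, title in zip(axes, ("samples", "OTU loadings")):
        ax.set_xlabel(f"PC1 ({100 * var['variance_fraction'][0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * var['variance_fraction'][1]:.1f}%)")
        ax.set_title(title)
        ax.axhline(0, color="k", lw=0.3)
        ax.axvline(0, color="k", lw=0.3)
    fig.tight_layout()
    path = out_dir / f"{prefix}_biplot.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def effect_strips(out_dir: Path) -> Path | None:
    """Strip plot of per-OTU effects for each successive group comparison."""
    path_in = out_dir / "effects_successive.tsv"
    if not path_in.exists():
        return None
    eff = pd.read_csv(path_in, sep="\t")
    pairs = eff[["group_a", "group_b"]].drop_duplicates().itertuples(index=False)
    pairs = list(pairs)
    fig, axes = plt.subplots(
        1, max(len(pairs), 1), figsize=(2.2 * max(len(pairs), 1), 4), sharex=True
    )
    axes = np.atleast_1d(axes)
    for ax, (a, b) in zip(axes, pairs):
        sub = eff[(eff["group_a"] == a) & (eff["group_b"] == b)]
        big = sub["effect"].abs() >= 1
        rng = np.random.default_rng(0)
        ys = rng.uniform(-0.3, 0.3, size=len(sub))
        ax.scatter(sub["effect"], ys, s=6, c=np.where(big, "crimson", "gray"))
        ax.axvline(1, color="k", ls=":", lw=0.6)
        ax.axvline(-1, color="k", ls=":", lw=0.6)
        ax.set_title(f"{a} vs {b}", fontsize=8)
        ax.set_yticks([])
        ax.set_xlabel("effect")
    fig.tight_layout()
    path = out_dir / "effects_strips.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def cluster_trends(out_dir: Path) -> Path | None:
    """Smoothed clr trend vs age for each rho cluster's member OTUs."""
    members_path = out_dir / "rho_clusters.tsv"
    div_path = out_dir / "diversity_age_trend.tsv"
    if not members_path.exists() or not div_path.exists():
        return None
    members = pd.read_csv(members_path, sep="\t")
    if members.empty:
        return None
    trend = pd.read_csv(div_path, sep="\t")
    clusters = list(members.groupby("cluster_id").groups)
    n = len(clusters) + 1
    fig, axes = plt.subplots(1, n, figsize=(2.5 * n, 3))
    axes = np.atleast_1d(axes)
    axes[0].plot(trend["age"], trend["smoothed"], color="k")
    axes[0].set_title("Shannon diversity vs age", fontsize=8)
    for ax, cid in zip(axes[1:], clusters):
        sub = members[members["cluster_id"] == cid]
        ax.set_title(f"cluster {cid} (n={len(sub)})", fontsize=8)
        ax.set_xlabel("age")
    fig.tight_layout()
    path = out_dir / "cluster_trends.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_all(out_dir: str | Path, group_column: str = "group") -> list[Path]:
    out_dir = Path(out_dir)
    made = []
    for fn in (
        lambda: biplot(out_dir, "pca_all", group_column),
        lambda: biplot(out_dir, "pca_selected", group_column),
        lambda: effect_strips(out_dir),
        lambda: cluster_trends(out_dir),
    ):
        p = fn()
        if p is not None:
            made.append(p)
    return made
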
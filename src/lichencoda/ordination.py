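"""Compositional PCA by SVD of the column-centered clr matrix.

The covariance biplot (alpha = 0) is the default display: variable arrows
are V * S^(1-alpha) / sqrt(n-1), so arrow inner products estimate clr
covariances and the squared link length between two arrowheads estimates
the variance of the corresponding pairwise log-ratio.  Pairwise "ratio
loadings" decompose each principal component's multiplicative influence on
every log-ratio: on PC k the additive loading of the pair (i, j) is
arrow_i,k - arrow_j,k and its exponential h_{ij,k} is the multiplicative
contribution plotted as bars around y = 1 (h = 1 means no influence, like a
zero loading in ordinary PCA).
"""
from __future__ import annotations

from dataclasses import dataclass, field
import itertools

import numpy as np
import pandas as pd

#: relative tolerance below which a singular value counts as numerically zero
RANK_TOL = 1e-10


@dataclass
class CompositionalPCA:
    """Raw SVD factors of the centered clr matrix plus bookkeeping."""

    U: np.ndarray                 # n x r
    singular_values: np.ndarray   # r, descending
    V: np.ndarray                 # D x r (right singular vectors, columns)
    centering: np.ndarray         # per-column means removed
    elements: tuple[str, ...]
    sample_ids: tuple[str, ...]
    biplot_alpha: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.U.shape[0]

    @property
    def var_explained(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        return s2 / s2.sum()

    @property
    def scores(self) -> pd.DataFrame:
        """Sample principal coordinates U*S (full rank retained)."""
        F = self.U * self.singular_values
        cols = [f"PC{k+1}" for k in range(F.shape[1])]
        return pd.DataFrame(F, index=list(self.sample_ids), columns=cols)

    @property
    def loadings(self) -> pd.DataFrame:
        cols = [f"PC{k+1}" for k in range(self.V.shape[1])]
        return pd.DataFrame(self.V, index=list(self.elements), columns=cols)

    def flip(self, k: int) -> None:
        """Flip the sign of component k (0-based) in scores and loadings."""
        self.U[:, k] = -self.U[:, k]
        self.V[:, k] = -self.V[:, k]


def compositional_pca(clr: pd.DataFrame) -> CompositionalPCA:
    """SVD of the column-centered clr matrix.

    Raises if the matrix has no variance (all rows identical).  The smallest
    singular value is ~0 by construction (clr rank deficiency).
    """
    X = clr.to_numpy(dtype=float)
    n, D = X.shape
    if n < 3 or D < 3:
        raise ValueError("need at least 3 samples and 3 elements")
    mu = X.mean(axis=0)
    Xc = X - mu
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValueError("constant matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return CompositionalPCA(
        U=U, singular_values=s, V=Vt.T, centering=mu,
        elements=tuple(clr.columns), sample_ids=tuple(map(str, clr.index)),
    )


def variance_explained(p: CompositionalPCA, k: int) -> float:
    """Cumulative proportion of total variance in the first k components."""
    r = len(p.singular_values)
    if not 1 <= k <= r:
        raise ValueError(f"k must be in [1, {r}]")
    return float(p.var_explained[:k].sum())


def biplot_coordinates(p: CompositionalPCA, alpha: float = 0.0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample points and variable arrows for PCs 1-2.

    alpha = 0 is the covariance biplot (variable structure faithful);
    alpha = 1 the form biplot (inter-sample distances faithful).  Arrows are
    scaled by 1 / sqrt(n-1) so that, at alpha = 0, arrow dot products
    estimate clr covariances.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    s = p.singular_values
    n = p.n_samples
    pts = p.U[:, :2] * s[:2] ** alpha
    arr = p.V[:, :2] * s[:2] ** (1.0 - alpha) / np.sqrt(n - 1)
    cols = ["PC1", "PC2"]
    return (pd.DataFrame(pts, index=list(p.sample_ids), columns=cols),
            pd.DataFrame(arr, index=list(p.elements), columns=cols))


def _arrow_matrix(p: CompositionalPCA) -> np.ndarray:
    """Covariance-scaled variable coordinates on all PCs (D x r)."""
    return p.V * p.singular_values / np.sqrt(p.n_samples - 1)


def ratio_loadings(p: CompositionalPCA, pcs: tuple[int, ...] = (1, 2)
                   ) -> pd.DataFrame:
    """Multiplicative contribution of each PC to each pairwise log-ratio.

    Returns a frame indexed by (numerator, denominator) pairs with one
    column per requested PC holding h = exp(arrow_num - arrow_den).
    h > 1: the PC pushes the ratio up; h = 1: no influence; reciprocal
    pairs satisfy h_ij * h_ji = 1.
    """
    r = len(p.singular_values)
    for k in pcs:
        if not 1 <= k <= r:
            raise ValueError(f"PC index {k} outside rank {r}")
    G = _arrow_matrix(p)
    els = list(p.elements)
    rows, idx = [], []
    for i, j in itertools.permutations(range(len(els)), 2):
        idx.append((els[i], els[j]))
        rows.append([np.exp(G[i, k - 1] - G[j, k - 1]) for k in pcs])
    out = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["num", "den"]),
        columns=[f"PC{k}" for k in pcs],
    )
    return out


def ratio_loading(p: CompositionalPCA, num: str, den: str, pc: int = 1) -> float:
    """h for one ordered element pair on one PC (h=1 for the self-ratio)."""
    els = list(p.elements)
    for e in (num, den):
        if e not in els:
            raise ValueError(f"unknown element {e!r}")
    G = _arrow_matrix(p)
    i, j = els.index(num), els.index(den)
    return float(np.exp(G[i, pc - 1] - G[j, pc - 1]))


# ---------------------------------------------------------------- plotting
def plot_biplot(p: CompositionalPCA, groups=None, alpha: float = 0.0, path=None):
    """Covariance biplot of PCs 1-2 (cosmetic; not part of the tested contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts, arr = biplot_coordinates(p, alpha)
    fig, ax = plt.subplots(figsize=(7, 6))
    if groups is not None:
        for g in pd.unique(pd.Series(groups)):
            m = np.asarray(pd.Series(groups) == g)
            ax.scatter(pts.values[m, 0], pts.values[m, 1], label=str(g), s=25)
        ax.legend()
    else:
        ax.scatter(pts["PC1"], pts["PC2"], s=25)
    scale = np.abs(pts.values).max() / max(np.abs(arr.values).max(), 1e-12)
    for e in arr.index:
        x, y = arr.loc[e] * scale
        ax.annotate(e, (x, y))
        ax.plot([0, x], [0, y], color="grey", lw=1)
    ve = p.var_explained * 100
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ratio_loadings(p: CompositionalPCA, pcs=(1, 2), path=None):
    """Barplot of multiplicative ratio loadings around y = 1 (cosmetic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rl = ratio_loadings(p, tuple(pcs))
    pairs = [(n, d) for n, d in rl.index if n < d]
    fig, axes = plt.subplots(len(pcs), 1, figsize=(9, 3 * len(pcs)),
                             squeeze=False)
    for ax, pc in zip(axes[:, 0], pcs):
        h = [rl.loc[(n, d), f"PC{pc}"] for n, d in pairs]
        ax.bar(range(len(pairs)), h)
        ax.axhline(1.0, color="k", lw=1)
        ax.set_yscale("log")
        ax.set_xticks(range(len(pairs)))
        ax.set_xticklabels([f"{n}/{d}" for n, d in pairs], rotation=90)
        ax.set_ylabel(f"PC{pc} multiplicative loading")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
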
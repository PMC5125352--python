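"""Multivariate group comparison in ilr coordinates.

MANOVA cannot be run on clr data (rows sum to zero, so the covariance matrix
is singular); the full-rank ilr coordinates are used instead.  Wilks' lambda
with Rao's F approximation provides the omnibus test; pairwise two-sample
Hotelling T^2 tests with Holm (default) or Bonferroni adjustment localize
the differences.  All statistics are invariant to the orthonormal ilr basis
chosen.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df: tuple[float, float]
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    dim: int


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


def manova_wilks(Z, groups) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda and Rao's F approximation.

    ``Z`` is an (n, p) matrix of ilr coordinates; ``groups`` aligned labels.
    Lambda = det(W) / det(W + B) with W and B the within- and between-group
    cross-product matrices.  Rao's transformation is exact for up to three
    groups or up to two response dimensions.
    """
    Z = np.asarray(Z, dtype=float)
    g = pd.Series(list(groups))
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n, p = Z.shape
    k = len(labels)
    counts = tuple(int((g == lab).sum()) for lab in labels)
    if n <= p + k:
        raise ValueError(
            "too few samples for the ilr dimension: reduce parts or add samples"
        )
    grand = Z.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab, m in zip(labels, counts):
        Xg = Z[np.asarray(g == lab)]
        mu = Xg.mean(axis=0)
        D = Xg - mu
        W += D.T @ D
        d = (mu - grand)[:, None]
        B += m * (d @ d.T)
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        raise ValueError("singular pooled within-group matrix: reduce dimension "
                         "or add samples")
    _, logdet_t = np.linalg.slogdet(W + B)
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    q = k - 1                      # hypothesis df
    ve = n - k                     # error df
    t = 1.0
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    w = ve + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return ManovaResult(lam, float(f), (df1, float(df2)), pval,
                        tuple(map(str, labels)), counts, p)


def hotelling_t2(A, B) -> HotellingResult:
    """Two-sample Hotelling T^2 with the pooled covariance.

    T^2 = (na*nb/(na+nb)) d' S_pooled^-1 d and
    F = T^2 (na+nb-p-1) / ((na+nb-2) p) on (p, na+nb-p-1) df.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na, p = A.shape
    nb = B.shape[0]
    if B.shape[1] != p:
        raise ValueError("dimension mismatch between groups")
    if na + nb <= p + 1:
        raise ValueError("too few samples for the dimension")
    d = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A, rowvar=False, ddof=1) if na > 1 else np.zeros((p, p))
    Sb = np.cov(B, rowvar=False, ddof=1) if nb > 1 else np.zeros((p, p))
    Sp = ((na - 1) * np.atleast_2d(Sa) + (nb - 1) * np.atleast_2d(Sb)) / (na + nb - 2)
    try:
        sol = np.linalg.solve(Sp, d)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular pooled covariance") from err
    t2 = float(na * nb / (na + nb) * d @ sol)
    df2 = na + nb - p - 1
    f = t2 * df2 / ((na + nb - 2) * p)
    pval = float(stats.f.sf(f, p, df2))
    return HotellingResult(t2, float(f), (p, df2), pval)


def adjust_pvalues(p_raw, method: str = "holm") -> np.ndarray:
    """Holm step-down (default) or plain Bonferroni adjustment, capped at 1."""
    p = np.asarray(list(p_raw), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown correction {method!r}")
    return multipletests(p, method=method)[1]


def pairwise_hotelling(Z, groups, method: str = "holm") -> pd.DataFrame:
    """All pairwise two-sample T^2 tests with multiplicity adjustment.

    Returns one row per unordered group pair with t2, F, df, raw and
    adjusted p, and the correction method used.
    """
    Z = np.asarray(Z, dtype=float)
    g = pd.Series(list(groups))
    labels = list(pd.unique(g))
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            res = hotelling_t2(Z[np.asarray(g == a)], Z[np.asarray(g == b)])
            rows.append({"group_a": a, "group_b": b, "t2": res.t2,
                         "f_stat": res.f_stat, "df1": res.df[0],
                         "df2": res.df[1], "p_raw": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_raw"], method)
    out["method"] = method
    return out
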
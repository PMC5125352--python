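"""Log-ratio machinery: closure, clr and ilr transforms and their inverses.

A composition x = [x1, ..., xD] carries only relative information.  The
centred log-ratio (clr) maps each part to ln(x_i / g(x)) where g is the
geometric mean of the parts; clr coordinates sum to zero, so the transformed
covariance matrix is singular.  The isometric log-ratio (ilr) maps to D-1
orthonormal coordinates (pivot / sequential-binary-partition basis)

    z_i = sqrt(i/(i+1)) * ln( (x_1 ... x_i)^(1/i) / x_{i+1} ),  i = 1..D-1,

which is an isometry of the clr geometry and full rank, making standard
multivariate tests applicable.  All products are computed in log space.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

#: tolerance for "clr coordinates sum to zero" checks
CLR_SUM_TOL = 1e-8

BASIS_TAG = "pivot-sbp"


def _as_positive_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D composition")
    if a.size < 3:
        raise ValueError("compositions need at least 3 parts")
    if not np.all(a > 0):
        raise ValueError("all parts must be strictly positive")
    return a


def geometric_mean_vector(x) -> float:
    """Geometric mean of the parts, (x1*...*xD)^(1/D), via log space."""
    a = _as_positive_array(x)
    return float(np.exp(np.mean(np.log(a))))


def clr_transform(x) -> np.ndarray:
    """clr(x)_i = ln(x_i / g(x)); output sums to zero."""
    a = _as_positive_array(x)
    la = np.log(a)
    return la - la.mean()


def clr_inverse(v, total: float = 1.0) -> np.ndarray:
    """Invert a clr vector, closing to the requested total.

    The coordinates must sum to ~0 (the clr image is the zero-sum hyperplane).
    """
    v = np.asarray(v, dtype=float)
    if abs(v.sum()) > CLR_SUM_TOL * max(1.0, np.abs(v).max()):
        raise ValueError("clr coordinates must sum to zero")
    e = np.exp(v - v.max())          # overflow-safe closure
    return total * e / e.sum()


def ilr_basis(D: int) -> np.ndarray:
    """Orthonormal (D, D-1) contrast matrix V of the pivot basis.

    Column i (0-based) has +sqrt(i+1/(i+2))/(i+1) on the first i+1 parts and
    -sqrt((i+1)/(i+2)) on part i+2, so ilr(x) = clr(x) @ V.
    """
    if D < 3:
        raise ValueError("need D >= 3")
    V = np.zeros((D, D - 1))
    for i in range(1, D):
        c = np.sqrt(i / (i + 1.0))
        V[:i, i - 1] = c / i
        V[i, i - 1] = -c
    return V


def ilr_transform(x) -> np.ndarray:
    """ilr in the pivot basis (panel order), a (D-1)-vector.

    Satisfies ||ilr(x)|| == ||clr(x)|| (isometry).
    """
    a = _as_positive_array(x)
    la = np.log(a)
    D = a.size
    out = np.empty(D - 1)
    csum = np.cumsum(la)
    for i in range(1, D):
        out[i - 1] = np.sqrt(i / (i + 1.0)) * (csum[i - 1] / i - la[i])
    return out


def ilr_inverse(z, total: float = 1.0) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    V = ilr_basis(z.size + 1)
    return clr_inverse(V @ z, total)  # clr vector = V z


def clr_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise clr of a samples x elements frame (errors name the row)."""
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 elements")
    bad = ~(arr > 0)
    if bad.any():
        r = int(np.argwhere(bad.any(axis=1))[0][0])
        raise ValueError(
            f"non-positive part in sample {values.index[r]!r}"
        )
    la = np.log(arr)
    out = la - la.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def ilr_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise ilr (pivot basis in column order) of a samples x elements frame."""
    C = clr_matrix(values)
    V = ilr_basis(values.shape[1])
    Z = C.to_numpy() @ V
    cols = [f"z{i+1}" for i in range(values.shape[1] - 1)]
    return pd.DataFrame(Z, index=values.index, columns=cols)
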
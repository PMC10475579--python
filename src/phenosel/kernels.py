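"""Relationship kernels from the feature matrix and from family membership.

GB is the linear kernel ``X X' / p`` of the standardized feature matrix; GK
is the Gaussian kernel ``exp(-h d^2 / q)`` with ``q`` the median off-diagonal
squared Euclidean distance; A is the constant within-family pedigree kernel.
Columns are standardized first (bands and indices live on wildly different
scales and both kernels are scale-sensitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class KernelMatrix:
    values: np.ndarray
    ids: list
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def subset(self, ids) -> "KernelMatrix":
        pos = {t: i for i, t in enumerate(self.ids)}
        try:
            idx = np.array([pos[t] for t in ids])
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not present in kernel") from e
        return KernelMatrix(
            self.values[np.ix_(idx, idx)], list(ids), self.kind, dict(self.params)
        )

    def block(self, row_ids, col_ids) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.ids)}
        ri = np.array([pos[t] for t in row_ids])
        ci = np.array([pos[t] for t in col_ids])
        return self.values[np.ix_(ri, ci)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def standardize(features: pd.DataFrame) -> pd.DataFrame:
    """Center/scale each column to mean 0, variance 1.

    NaN cells are imputed to the column mean first (count recorded in
    ``.attrs['n_imputed']`` and warned); zero-variance columns are dropped
    with a warning.  All-NaN columns are an error.
    """
    if len(features) < 2:
        raise ValueError("standardize requires >= 2 rows")
    X = features.copy()
    all_nan = [c for c in X.columns if X[c].isna().all()]
    if all_nan:
        raise ValueError(f"all-NaN column(s): {all_nan}")
    n_imputed = int(X.isna().to_numpy().sum())
    if n_imputed:
        warnings.warn(
            f"imputed {n_imputed} NaN cell(s) to column means", RuntimeWarning
        )
        X = X.fillna(X.mean())
    sd = X.std(ddof=0)
    dropped = [c for c in X.columns if sd[c] == 0 or not np.isfinite(sd[c])]
    if dropped:
        warnings.warn(f"dropped zero-variance column(s): {dropped}", RuntimeWarning)
        X = X.drop(columns=dropped)
    out = (X - X.mean()) / X.std(ddof=0)
    out.attrs["n_imputed"] = n_imputed
    out.attrs["dropped"] = dropped
    out.attrs.setdefault("month", features.attrs.get("month"))
    return out


def gb_kernel(X: pd.DataFrame) -> KernelMatrix:
    """Linear kernel ``X X' / p`` of a standardized feature matrix."""
    p = X.shape[1]
    if p == 0:
        raise ValueError("no feature columns left to build a kernel from")
    M = X.to_numpy(dtype=float)
    K = M @ M.T / p
    K = (K + K.T) / 2
    return KernelMatrix(K, list(X.index), "GB", {"p": p})


def gk_kernel(X: pd.DataFrame, h: float = 1.0) -> KernelMatrix:
    """Gaussian kernel ``exp(-h d^2 / q)``; ``q`` is the median off-diagonal
    squared distance.  All-identical rows give an all-ones kernel with a
    warning.  Diagonal is exactly 1."""
    if h <= 0:
        raise ValueError(f"bandwidth h must be > 0, got {h}")
    if len(X) < 2:
        raise ValueError("gk_kernel requires >= 2 rows")
    d2 = pdist(X.to_numpy(dtype=float), metric="sqeuclidean")
    q = float(np.median(d2))
    if q == 0:
        warnings.warn(
            "all feature rows identical (q = 0); returning all-ones kernel",
            RuntimeWarning,
        )
        K = np.ones((len(X), len(X)))
    else:
        K = squareform(np.exp(-h * d2 / q))
        np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, list(X.index), "GK", {"h": h, "q": q, "p": X.shape[1]})


def pedigree_kernel(trees, rho: float = 0.4) -> KernelMatrix:
    """Constant within-family relatedness kernel.

    ``trees`` is a list of TreeRecord or a DataFrame with ``tree_id`` and
    ``family`` columns.  ``A_ii = 1``, ``A_ij = rho`` for same-family pairs,
    0 otherwise.  The default ``rho = 1/2.5`` matches the heritability
    coefficient used for open-pollinated families.
    """
    if not (0 <= rho <= 1):
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if isinstance(trees, pd.DataFrame):
        ids = trees["tree_id"].tolist()
        fams = trees["family"].tolist()
    else:
        ids = [t.tree_id for t in trees]
        fams = [t.family_id for t in trees]
    fam = np.asarray(fams, dtype=object)
    same = fam[:, None] == fam[None, :]
    K = np.where(same, rho, 0.0)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, ids, "A", {"rho": rho})


def write_kernel(kernel: KernelMatrix, path: str) -> None:
    """Square CSV with id header row/column; params in a sidecar JSON."""
    import json
    import os

    kernel.to_dataframe().to_csv(path, float_format="%.12g")
    base, _ = os.path.splitext(path)
    with open(base + ".json", "w", encoding="utf-8") as fh:
        json.dump({"kind": kernel.kind, "params": kernel.params}, fh, indent=1)


def read_kernel(path: str) -> KernelMatrix:
    import json
    import os

    df = pd.read_csv(path, index_col=0)
    base, _ = os.path.splitext(path)
    kind, params = "GB", {}
    if os.path.exists(base + ".json"):
        with open(base + ".json", encoding="utf-8") as fh:
            meta = json.load(fh)
        kind, params = meta.get("kind", kind), meta.get("params", params)
    return KernelMatrix(df.to_numpy(), list(df.index), kind, params)
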
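"""Vegetation indices from five-band canopy reflectance.

The camera provides blue (450 nm), green (560 nm), red (650 nm), red-edge
(730 nm) and near-infrared (840 nm) reflectances per tree.  Fifteen indices
are derived from them; together with the raw bands they form the 20-column
feature matrix that stands in for a marker matrix downstream.

Degenerate denominators produce NaN (with a warning), never an exception:
real reflectance tables contain dropouts and a single bad pixel must not
abort a scan.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Nominal band centers (nm) used by TGI's wavelength constants.
LAMBDA_BLUE = 450.0
LAMBDA_GREEN = 560.0
LAMBDA_RED = 650.0

BAND_COLUMNS = ("blue", "green", "red", "rededge", "nir")

INDEX_COLUMNS = (
    "NDVI",
    "OSAVI",
    "GNDVI",
    "SAVI",
    "MSAVI",
    "TGI",
    "GLI",
    "TVI",
    "RECI",
    "LCI",
    "ARI",
    "MGRVI",
    "MARI",
    "NDRE",
    "RGBVI",
)

#: Column order of the full feature matrix: 5 bands then the 15 indices.
FEATURE_COLUMNS = BAND_COLUMNS + INDEX_COLUMNS


def _safe_divide(num, den, name):
    """Elementwise num/den with NaN (and a warning) where den == 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = den == 0
    if np.any(bad):
        warnings.warn(
            f"{name}: {int(np.count_nonzero(bad))} zero denominator(s) -> NaN",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out


def compute_indices(blue, green, red, rededge, nir) -> dict[str, np.ndarray]:
    """Evaluate all 15 vegetation indices from band reflectances.

    Parameters are scalars or equal-length arrays.  Returns a dict keyed by
    index name in :data:`INDEX_COLUMNS` order.  Zero denominators (and a
    negative MSAVI discriminant) give NaN with a RuntimeWarning.
    """
    B = np.asarray(blue, dtype=float)
    G = np.asarray(green, dtype=float)
    R = np.asarray(red, dtype=float)
    E = np.asarray(rededge, dtype=float)
    N = np.asarray(nir, dtype=float)

    out: dict[str, np.ndarray] = {}
    out["NDVI"] = _safe_divide(N - R, N + R, "NDVI")
    out["OSAVI"] = _safe_divide((N - R) * (1 + 0.16), N + R + 0.16, "OSAVI")
    out["GNDVI"] = _safe_divide(N - G, N + G, "GNDVI")
    out["SAVI"] = _safe_divide((N - R) * (1 + 0.5), N + R + 0.5, "SAVI")

    disc = (2 * N + 1) ** 2 - 8 * (N - R)
    neg = disc < 0
    if np.any(neg):
        warnings.warn(
            f"MSAVI: {int(np.count_nonzero(neg))} negative discriminant(s) -> NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out["MSAVI"] = (2 * N + 1 - np.sqrt(np.where(neg, np.nan, disc))) / 2

    out["TGI"] = np.asarray(
        -0.5
        * (
            (LAMBDA_RED - LAMBDA_BLUE) * (R - G)
            - (LAMBDA_RED - LAMBDA_GREEN) * (R - B)
        )
    )
    out["GLI"] = _safe_divide(2 * G - R - B, 2 * G + R + B, "GLI")
    out["TVI"] = np.asarray(0.5 * (120 * (N - G) - 200 * (R - G)))
    out["RECI"] = _safe_divide(N, E, "RECI") - 1
    out["LCI"] = _safe_divide(N - E, N + R, "LCI")
    # Literal definition used here: green over NIR (not the classical
    # reciprocal-difference form).
    out["ARI"] = _safe_divide(G, N, "ARI")
    out["MGRVI"] = _safe_divide(G**2 - R**2, G**2 + R**2, "MGRVI")
    ginv = _safe_divide(np.ones_like(G), G, "MARI")
    einv = _safe_divide(np.ones_like(E), E, "MARI")
    out["MARI"] = _safe_divide(ginv - einv, N, "MARI")
    out["NDRE"] = _safe_divide(N - E, N + E, "NDRE")
    out["RGBVI"] = _safe_divide(G**2 - R * B, G**2 + R * B, "RGBVI")
    return out


def build_feature_matrix(observations: pd.DataFrame, month: str) -> pd.DataFrame:
    """Assemble the per-month tree-by-variable feature matrix.

    ``observations`` is the long table with one row per (tree, month) and the
    five band columns.  Returns a DataFrame indexed by ``tree_id`` with the 20
    columns of :data:`FEATURE_COLUMNS`; rows with NaN indices are retained
    (imputation is the kernel builder's job).  The month label is recorded in
    ``.attrs['month']``.
    """
    missing = [c for c in BAND_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"observations missing band column(s): {missing}")
    if "month" not in observations.columns or "tree_id" not in observations.columns:
        raise ValueError("observations must have 'tree_id' and 'month' columns")
    months_present = observations["month"].unique()
    if month not in months_present:
        raise ValueError(
            f"month {month!r} not present in observations "
            f"(have: {sorted(map(str, months_present))})"
        )
    sl = observations.loc[observations["month"] == month]
    sl = sl.sort_values("tree_id").set_index("tree_id")
    bands = {c: sl[c].to_numpy(dtype=float) for c in BAND_COLUMNS}
    vis = compute_indices(
        bands["blue"], bands["green"], bands["red"], bands["rededge"], bands["nir"]
    )
    mat = pd.DataFrame(index=sl.index)
    for c in BAND_COLUMNS:
        mat[c] = bands[c]
    for c in INDEX_COLUMNS:
        mat[c] = np.atleast_1d(vis[c])
    mat.attrs["month"] = month
    return mat
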
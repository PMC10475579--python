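"""Per-month association scan of spectral variables against growth traits.

Each month plays the role of a chromosome and each of the 20 feature columns
the role of a marker.  For a given trait-month, block/family variance
components are estimated once by REML under the null model (no marker), and
every variable is then tested by generalized least squares at those
estimates — the standard two-stage mixed-model association strategy, with
the family random effect playing the part of the kinship correction.  Hits
are flagged at a fixed threshold (strict inequality) with no
multiple-testing correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phenosel.genetics import _incidence, reml_em
from phenosel.phenopred import TRAIT_COLUMNS
from phenosel.vegindices import FEATURE_COLUMNS, build_feature_matrix


@dataclass
class AssociationRecord:
    month: str
    variable: str
    trait: str
    beta: float
    se: float
    p_value: float
    significant: bool

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


@dataclass
class ScanResult:
    records: pd.DataFrame  # month, variable, trait, beta, se, p_value, ...
    threshold: float = 1e-3
    counts: dict = field(default_factory=dict)


@dataclass
class NullStructure:
    """REML-fitted block/family covariance of one trait-month, cached as a
    dense inverse for fast per-variable GLS."""

    Vinv: np.ndarray
    sigma2_b: float
    sigma2_f: float
    sigma2_e: float
    n: int
    converged: bool


def fit_null_structure(
    y: np.ndarray,
    blocks,
    families,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> NullStructure:
    """Estimate block/family/residual components of ``y`` (no marker term)
    and cache V^-1 at the estimates."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    Zb, _ = _incidence(pd.Series(blocks))
    Zf, _ = _incidence(pd.Series(families))
    res = reml_em(
        y, np.ones((n, 1)), [Zb, Zf], tol=tol, max_iter=max_iter,
        names=("block", "family"),
    )
    s2b, s2f = res["sigma2_raw"]
    s2e = res["sigma2_e"]
    V = s2b * (Zb @ Zb.T) + s2f * (Zf @ Zf.T) + s2e * np.eye(n)
    Vinv = np.linalg.inv(V)
    return NullStructure(
        Vinv=Vinv, sigma2_b=s2b, sigma2_f=s2f, sigma2_e=s2e, n=n,
        converged=res["converged"],
    )


def association_test(
    y: np.ndarray,
    x: np.ndarray,
    structure: NullStructure | None,
    month: str = "",
    variable: str = "",
    trait: str = "",
    threshold: float = 1e-3,
) -> AssociationRecord:
    """Two-sided Wald test of the marker slope.

    With a :class:`NullStructure` the test is GLS at the REML estimates
    (mixed-model corrected); with ``structure=None`` it is a naive ordinary
    regression.  Zero-variance ``x`` yields NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    if float(np.std(x)) == 0:
        warnings.warn(f"zero-variance predictor {variable!r}: p = NaN", RuntimeWarning)
        return AssociationRecord(month, variable, trait, float("nan"), float("nan"),
                                 float("nan"), False)
    X = np.column_stack([np.ones(n), x])
    if structure is None:
        Vinv_X = X
        Vinv_y = y
    else:
        if structure.n != n or (not np.all(ok)):
            raise ValueError("structure was fitted on a different set of cases")
        Vinv_X = structure.Vinv @ X
        Vinv_y = structure.Vinv @ y
    A = X.T @ Vinv_X
    b = X.T @ Vinv_y
    cov = np.linalg.inv(A)
    coef = cov @ b
    if structure is None:
        resid = y - X @ coef
        s2 = float(resid @ resid) / (n - 2)
        cov = cov * s2
    beta = float(coef[1])
    se = float(math.sqrt(cov[1, 1]))
    tval = beta / se
    p = float(2 * stats.t.sf(abs(tval), df=n - 2))
    p = max(p, 1e-300)
    return AssociationRecord(
        month, variable, trait, beta, se, p, bool(p < threshold)
    )


def scan(
    data,
    threshold: float = 1e-3,
    structure: bool = True,
    months: list[str] | None = None,
    traits: tuple[str, ...] = ("height", "crown_area"),
) -> ScanResult:
    """Test every (month, variable, trait) combination.

    Features are standardized per month before testing so slopes are
    per-standard-deviation and comparable across variables.  Missing months
    are skipped with a warning.
    """
    obs = data.observations
    tf = data.trees_frame().set_index("tree_id")
    present = list(pd.unique(obs["month"]))
    if months is None:
        months = present
    records = []
    for month in months:
        if month not in present:
            warnings.warn(f"month {month!r} absent from observations; skipped",
                          RuntimeWarning)
            continue
        feats = build_feature_matrix(obs, month)
        ids = list(feats.index)
        sl = obs.loc[obs["month"] == month].set_index("tree_id").loc[ids]
        blocks = tf.loc[ids, "block"].to_numpy()
        fams = tf.loc[ids, "family"].to_numpy()
        fmean = feats.mean()
        fstd = feats.std(ddof=0)
        for trait in traits:
            y = sl[TRAIT_COLUMNS.get(trait, trait)].to_numpy(dtype=float)
            ns = fit_null_structure(y, blocks, fams) if structure else None
            for variable in FEATURE_COLUMNS:
                xv = feats[variable].to_numpy(dtype=float)
                if fstd[variable] > 0:
                    xv = (xv - fmean[variable]) / fstd[variable]
                rec = association_test(
                    y, xv, ns, month=month, variable=variable, trait=trait,
                    threshold=threshold,
                )
                records.append(rec)
    df = pd.DataFrame(
        {
            "month": [r.month for r in records],
            "variable": [r.variable for r in records],
            "trait": [r.trait for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p_value": [r.p_value for r in records],
        }
    )
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_value"])
    df["significant"] = df["p_value"] < threshold
    counts = df.groupby("trait")["significant"].sum().astype(int).to_dict()
    return ScanResult(records=df, threshold=threshold, counts=counts)


def manhattan_table(result: ScanResult) -> pd.DataFrame:
    """Plot-ready table: chromosome = month, position = variable index
    (1..20).  The -log10 threshold line value is in ``.attrs``."""
    df = result.records
    if len(df) == 0:
        raise ValueError("empty scan result")
    pos = {v: i + 1 for i, v in enumerate(FEATURE_COLUMNS)}
    out = pd.DataFrame(
        {
            "chromosome": df["month"],
            "position": df["variable"].map(pos),
            "neg_log10_p": df["neg_log10_p"],
            "trait": df["trait"],
        }
    )
    out.attrs["threshold_line"] = -math.log10(result.threshold)
    return out
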
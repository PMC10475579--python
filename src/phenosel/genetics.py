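"""REML genetic parameters for the family/block mixed model.

Per trait and month the model is

    y = mu (+ site) + block + family + e

with independent Gaussian block and family effects.  Variance components are
estimated by EM-type REML updates built on Henderson's mixed-model equations
(monotone in the restricted likelihood, non-negative by construction).  From
the fitted components come heritability, family breeding values (BLUPs),
rankings, genetic correlations via the sum-trait identity, and genetic gain
at a selection fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = math.log(2 * math.pi)


@dataclass
class MixedModelSpec:
    """One trait-month slice ready for REML.

    ``data`` must have columns ``response``, ``block`` and ``family`` (and
    ``site`` when ``site_fixed``).  Rows with NaN response are dropped.
    """

    response: str
    data: pd.DataFrame
    site_fixed: bool = False
    trait: str = ""
    month: str = ""

    def __post_init__(self):
        if not self.trait:
            self.trait = self.response


@dataclass
class VarianceComponents:
    sigma2_f: float
    sigma2_b: float
    sigma2_e: float
    converged: bool
    n_iter: int
    rll: float = float("nan")
    trait: str = ""
    month: str = ""
    rll_history: list = field(default_factory=list, repr=False)


@dataclass
class HeritabilityEstimate:
    h2: float
    coefficient: float = 2.5
    trait: str = ""
    month: str = ""


@dataclass
class FamilyRanking:
    """Family BLUPs with deterministic descending-BLUP ranks."""

    table: pd.DataFrame  # columns: family, blup, deviation, rank
    trait: str = ""
    month: str = ""


def _incidence(labels: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(labels, sort=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, list(levels)


def _restricted_loglik(n, p, q_list, s2_list, s2e, logdetM, yPy) -> float:
    # log|V| + log|X'V^-1 X| = (n-p-q)log s2e + sum q_k log s2_k + log|M|
    # with M the MME coefficient matrix; yPy already divided by s2e.
    q = sum(q_list)
    ld = (n - p - q) * math.log(s2e) + sum(
        qk * math.log(sk) for qk, sk in zip(q_list, s2_list)
    )
    return -0.5 * ((n - p) * _LOG2PI + ld + logdetM + yPy)


def reml_em(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 500,
    names: tuple[str, ...] | None = None,
):
    """EM-REML for ``y = X b + sum_k Z_k u_k + e`` with iid random effects.

    Returns a dict with variance components (one per Z plus residual), the
    fixed-effect solution, BLUPs, the restricted log-likelihood trace, and
    convergence info.  Components are floored at a tiny positive value so the
    mixed-model equations stay well posed; a floored component is reported as
    is (effectively zero).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design matrix X")
    names = names or tuple(f"u{k}" for k in range(len(Z_list)))
    for nm, Z in zip(names, Z_list):
        if Z.shape[1] < 2:
            raise ValueError(f"random factor {nm!r} has < 2 levels (singular design)")

    W = np.hstack([X] + Z_list)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    q_list = [Z.shape[1] for Z in Z_list]
    starts = np.cumsum([p] + q_list)[:-1]

    vary = float(np.var(y)) or 1.0
    floor = 1e-8 * vary
    K = len(Z_list)
    s2 = [vary / (K + 1)] * K
    s2e = vary / (K + 1)

    rll_prev = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = np.zeros(W.shape[1])
        for k in range(K):
            lam[starts[k] : starts[k] + q_list[k]] = s2e / s2[k]
        M = WtW + np.diag(lam)
        cf = cho_factor(M, lower=True)
        s = cho_solve(cf, Wty)
        Minv = cho_solve(cf, np.eye(M.shape[0]))
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = (yty - float(s @ Wty)) / s2e
        rll = _restricted_loglik(n, p, q_list, s2, s2e, logdetM, yPy)
        history.append(rll)
        if abs(rll - rll_prev) < tol:
            converged = True
            break
        rll_prev = rll

        new_s2 = []
        for k in range(K):
            sl = slice(starts[k], starts[k] + q_list[k])
            uk = s[sl]
            tr = float(np.trace(Minv[sl, sl]))
            new_s2.append(max((float(uk @ uk) + s2e * tr) / q_list[k], floor))
        s2e = max((yty - float(s @ Wty)) / (n - p), floor)
        s2 = new_s2

    beta = s[:p]
    u_list = [s[starts[k] : starts[k] + q_list[k]].copy() for k in range(K)]
    return {
        "sigma2": [0.0 if v <= floor * (1 + 1e-12) else v for v in s2],
        "sigma2_raw": list(s2),
        "sigma2_e": s2e,
        "beta": beta,
        "u": u_list,
        "rll": history[-1],
        "rll_history": history,
        "converged": converged,
        "n_iter": it,
        "names": names,
    }


def _prepare(spec: MixedModelSpec):
    need = [spec.response, "block", "family"]
    if spec.site_fixed:
        need.append("site")
    missing = [c for c in need if c not in spec.data.columns]
    if missing:
        raise ValueError(f"data missing column(s): {missing}")
    d = spec.data.dropna(subset=[spec.response])
    if len(d) == 0:
        raise ValueError(f"all observations missing for {spec.response!r}")
    y = d[spec.response].to_numpy(dtype=float)
    Zb, blocks = _incidence(d["block"])
    Zf, fams = _incidence(d["family"])
    if len(fams) < 2:
        raise ValueError("need >= 2 families")
    if len(blocks) < 2:
        raise ValueError("need >= 2 blocks")
    X = np.ones((len(d), 1))
    if spec.site_fixed:
        Zs, sites = _incidence(d["site"])
        X = np.hstack([X, Zs[:, 1:]])  # first site level absorbed by the mean
    return y, X, [Zb, Zf], blocks, fams


def fit_variance_components(
    spec: MixedModelSpec, tol: float = 1e-8, max_iter: int = 500
) -> VarianceComponents:
    """REML block/family/residual variance components for one trait-month."""
    y, X, Zs, _, _ = _prepare(spec)
    res = reml_em(y, X, Zs, tol=tol, max_iter=max_iter, names=("block", "family"))
    if not res["converged"]:
        warnings.warn(
            f"REML did not converge in {res['n_iter']} iterations "
            f"({spec.trait}/{spec.month})",
            RuntimeWarning,
        )
    return VarianceComponents(
        sigma2_f=res["sigma2"][1],
        sigma2_b=res["sigma2"][0],
        sigma2_e=res["sigma2_e"],
        converged=res["converged"],
        n_iter=res["n_iter"],
        rll=res["rll"],
        trait=spec.trait,
        month=spec.month,
        rll_history=res["rll_history"],
    )


def heritability(
    vc: VarianceComponents, coefficient: float = 2.5, include_block: bool = True
) -> HeritabilityEstimate:
    """Narrow-sense heritability ``coefficient * s2_f / (s2_f + s2_b + s2_e)``.

    The denominator includes the block variance by default; ``include_block=
    False`` switches to a phenotypic variance without it.
    """
    denom = vc.sigma2_f + vc.sigma2_e + (vc.sigma2_b if include_block else 0.0)
    if denom <= 0:
        warnings.warn("all variance components are zero; h2 set to 0", RuntimeWarning)
        h2 = 0.0
    else:
        h2 = coefficient * vc.sigma2_f / denom
    return HeritabilityEstimate(
        h2=h2, coefficient=coefficient, trait=vc.trait, month=vc.month
    )


def genetic_correlation(
    vc_i: VarianceComponents, vc_j: VarianceComponents, cov_ij: float
) -> float:
    """Family-effect correlation ``cov_ij / sqrt(s2_fi * s2_fj)``, clipped to
    [-1, 1] with a warning when numerically outside."""
    if vc_i.sigma2_f <= 0 or vc_j.sigma2_f <= 0:
        warnings.warn(
            "genetic correlation undefined: zero family variance", RuntimeWarning
        )
        return float("nan")
    r = cov_ij / math.sqrt(vc_i.sigma2_f * vc_j.sigma2_f)
    if abs(r) > 1:
        warnings.warn(
            f"genetic correlation {r:.4f} outside [-1, 1]; clipped", RuntimeWarning
        )
        r = max(-1.0, min(1.0, r))
    return r


def family_covariance(
    data: pd.DataFrame,
    trait_i: str,
    trait_j: str,
    site_fixed: bool = False,
    **kw,
) -> tuple[VarianceComponents, VarianceComponents, float]:
    """Family covariance between two traits via the sum-trait identity.

    Both traits are measured on the same individuals, so
    ``Var_f(i + j) = Var_f(i) + Var_f(j) + 2 Cov_f(i, j)`` and the covariance
    follows from three univariate REML fits.
    """
    d = data.dropna(subset=[trait_i, trait_j]).copy()
    d["_sum"] = d[trait_i] + d[trait_j]
    vi = fit_variance_components(
        MixedModelSpec(trait_i, d, site_fixed=site_fixed, trait=trait_i), **kw
    )
    vj = fit_variance_components(
        MixedModelSpec(trait_j, d, site_fixed=site_fixed, trait=trait_j), **kw
    )
    vs = fit_variance_components(
        MixedModelSpec("_sum", d, site_fixed=site_fixed, trait="_sum"), **kw
    )
    cov = 0.5 * (vs.sigma2_f - vi.sigma2_f - vj.sigma2_f)
    return vi, vj, cov


def family_breeding_values(
    spec: MixedModelSpec, tol: float = 1e-8, max_iter: int = 500
) -> FamilyRanking:
    """Family-effect BLUPs at the REML estimates, ranked descending.

    BLUPs are deviations from the overall mean by construction; ties are
    broken by family id.
    """
    y, X, Zs, _, fams = _prepare(spec)
    res = reml_em(y, X, Zs, tol=tol, max_iter=max_iter, names=("block", "family"))
    blup = res["u"][1]
    tab = pd.DataFrame({"family": fams, "blup": blup})
    tab["deviation"] = tab["blup"]
    tab = tab.sort_values(["blup", "family"], ascending=[False, True]).reset_index(
        drop=True
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab = tab.sort_values("family").reset_index(drop=True)
    return FamilyRanking(table=tab, trait=spec.trait, month=spec.month)


def genetic_gain(
    ranking: FamilyRanking, r: float, literal_form: bool = False
) -> float:
    """Genetic gain at selection fraction ``r``.

    Default: mean breeding value of the top ``ceil(r * n)`` families minus
    the mean breeding value of all families.  ``literal_form=True`` instead
    multiplies the selected mean by ``r`` before subtracting (the printed
    formula read literally); the default follows the verbal definition.
    """
    if not (0 < r <= 1):
        raise ValueError(f"selection fraction must be in (0, 1], got {r}")
    bv = ranking.table.sort_values(["blup", "family"], ascending=[False, True])[
        "blup"
    ].to_numpy()
    k = math.ceil(r * len(bv))
    mbv = float(np.mean(bv[:k]))
    tbv = float(np.mean(bv))
    return mbv * r - tbv if literal_form else mbv - tbv
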
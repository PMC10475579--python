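"""Phenomic prediction: kernel BLUP and repeated 80/20 cross-validation.

Fits ``y = 1 mu + sum_k u_k + e`` with ``u_k ~ N(0, K_k s2_k)`` by REML.
Single-kernel models use an exact eigendecomposition profile (fast enough to
re-fit hundreds of CV splits); two-kernel models maximize the restricted
likelihood over log-variances numerically.  Out-of-sample prediction is the
conditional-mean projection ``mu + sum_k K_k[test, train] alpha_k``, which
coincides with the BLUP of masked records in the joint system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from phenosel.kernels import KernelMatrix, gb_kernel, gk_kernel, pedigree_kernel, standardize
from phenosel.vegindices import build_feature_matrix

_LOG2PI = math.log(2 * math.pi)

#: Map trait keys to observation columns.
TRAIT_COLUMNS = {"height": "height_m", "crown_area": "crown_area_m2"}


@dataclass
class CVConfig:
    train_fraction: float = 0.8
    n_reps: int = 100
    seed: int = 0
    models: tuple[str, ...] = ("GB", "GK")
    split: str = "tree"  # or "family"
    h: float = 1.0
    rho: float = 0.4

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.split not in ("tree", "family"):
            raise ValueError(f"unknown split mode {self.split!r}")
        bad = [m for m in self.models if m not in ("GB", "GK", "GB+P", "GK+P")]
        if bad:
            raise ValueError(f"unknown model(s): {bad}")


@dataclass
class KernelModelFit:
    kernels: list[KernelMatrix]
    train_ids: list
    sigma2_u: list[float]
    sigma2_e: float
    intercept: float
    alpha: np.ndarray  # V^-1 (y - mu) on the training set
    blups: list[np.ndarray]
    fitted: np.ndarray
    residuals: np.ndarray
    reml_converged: bool
    rll: float


@dataclass
class CVSummary:
    month: str
    trait: str
    model: str
    mean_r: float
    sd_r: float
    n_reps: int
    n_skipped: int = 0


@dataclass
class CVResult:
    summaries: list[CVSummary]
    per_rep: pd.DataFrame = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])


def _check_psd(K: np.ndarray, kind: str) -> None:
    w = np.linalg.eigvalsh(K)
    if w[0] < -1e-8:
        raise ValueError(
            f"kernel {kind!r} is not PSD (min eigenvalue {w[0]:.3e} after jitter)"
        )


def _fit_single_kernel(y: np.ndarray, K: np.ndarray, tol: float = 1e-9):
    """Exact REML for one kernel + residual via eigendecomposition."""
    n = len(y)
    lam, U = np.linalg.eigh((K + K.T) / 2)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    vary = float(np.var(y))
    if vary == 0:
        return {
            "s2_u": 0.0,
            "s2_e": 0.0,
            "mu": float(np.mean(y)),
            "alpha": np.zeros(n),
            "rll": float("nan"),
            "converged": True,
        }

    def neg_profile(t):
        d = math.pow(10.0, t) * lam + 1.0
        a = 1.0 / d
        xvx = float(np.sum(a * xt * xt))
        xvy = float(np.sum(a * xt * yt))
        yvy = float(np.sum(a * yt * yt))
        ypy = yvy - xvy * xvy / xvx
        s2e = max(ypy / (n - 1), 1e-300)
        rll = -0.5 * (
            (n - 1) * (_LOG2PI + math.log(s2e) + 1.0)
            + float(np.sum(np.log(d)))
            + math.log(xvx)
        )
        return -rll

    res = minimize_scalar(
        neg_profile, bounds=(-8.0, 8.0), method="bounded", options={"xatol": 1e-9}
    )
    t = res.x
    # boundary handling: treat delta ~ 1e-8 as a zero-variance kernel
    cand = [(neg_profile(tt), tt) for tt in (-8.0, t)]
    t = min(cand)[1]
    delta = math.pow(10.0, t)
    d = delta * lam + 1.0
    a = 1.0 / d
    xvx = float(np.sum(a * xt * xt))
    xvy = float(np.sum(a * xt * yt))
    mu = xvy / xvx
    rt = yt - mu * xt
    ypy = float(np.sum(a * rt * rt))
    s2e = ypy / (n - 1)
    s2u = delta * s2e
    if t <= -7.999:
        s2u = 0.0
    alpha = U @ (a * rt) / s2e if s2e > 0 else np.zeros(n)
    rll = -neg_profile(math.log10(delta) if delta > 0 else -8.0)
    return {
        "s2_u": s2u,
        "s2_e": s2e,
        "mu": mu,
        "alpha": alpha,
        "rll": rll,
        "converged": bool(res.success),
    }


def _rll_dense(y, Ks, s2s, s2e):
    n = len(y)
    V = s2e * np.eye(n)
    for K, s2 in zip(Ks, s2s):
        V += s2 * K
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    one = np.ones(n)
    Vy = cho_solve(cf, y)
    V1 = cho_solve(cf, one)
    xvx = float(one @ V1)
    mu = float(one @ Vy) / xvx
    r = y - mu
    ypy = float(r @ cho_solve(cf, r))
    rll = -0.5 * ((n - 1) * _LOG2PI + logdetV + math.log(xvx) + ypy)
    return rll, (mu, cf)


def _fit_multi_kernel(y: np.ndarray, Ks: list[np.ndarray], tol: float = 1e-8):
    n = len(y)
    vary = float(np.var(y))
    if vary == 0:
        return {
            "s2_u": [0.0] * len(Ks),
            "s2_e": 0.0,
            "mu": float(np.mean(y)),
            "alpha": np.zeros(n),
            "rll": float("nan"),
            "converged": True,
        }
    nk = len(Ks)

    def neg(theta):
        s2 = np.exp(np.clip(theta, -30, 30)) * vary
        rll, _ = _rll_dense(y, Ks, s2[:nk], s2[nk])
        return -rll if np.isfinite(rll) else 1e12

    x0 = np.full(nk + 1, math.log(1.0 / (nk + 1)))
    res = minimize(
        neg,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": tol, "maxiter": 4000, "maxfev": 6000},
    )
    s2 = np.exp(np.clip(res.x, -30, 30)) * vary
    s2s, s2e = list(s2[:nk]), float(s2[nk])
    rll, aux = _rll_dense(y, Ks, s2s, s2e)
    mu, cf = aux
    alpha = cho_solve(cf, y - mu)
    return {
        "s2_u": s2s,
        "s2_e": s2e,
        "mu": mu,
        "alpha": alpha,
        "rll": rll,
        "converged": bool(res.success),
    }


def fit_kernel_blup(
    y: pd.Series, kernels, tol: float = 1e-8
) -> KernelModelFit:
    """REML fit of the kernel BLUP model on the phenotyped (training) trees.

    ``y`` is indexed by tree id; each kernel must cover those ids (it may
    cover more — the extra trees are the prediction targets).
    """
    if isinstance(kernels, KernelMatrix):
        kernels = [kernels]
    kernels = list(kernels)
    if not 1 <= len(kernels) <= 2:
        raise ValueError("fit_kernel_blup supports 1 or 2 kernels")
    train_ids = list(y.index)
    yv = y.to_numpy(dtype=float)
    Ks = []
    for k in kernels:
        sub = k.subset(train_ids).values
        sub = sub + 1e-8 * np.eye(len(sub))
        _check_psd(sub, k.kind)
        Ks.append(sub)

    if len(Ks) == 1:
        res = _fit_single_kernel(yv, Ks[0], tol=tol)
        s2s = [res["s2_u"]]
    else:
        res = _fit_multi_kernel(yv, Ks, tol=tol)
        s2s = res["s2_u"]
    if not res["converged"]:
        warnings.warn("kernel REML did not converge", RuntimeWarning)
    alpha = res["alpha"]
    blups = [s2 * (K @ alpha) for s2, K in zip(s2s, Ks)]
    fitted = res["mu"] + np.sum(blups, axis=0) if blups else np.full(len(yv), res["mu"])
    residuals = yv - fitted
    return KernelModelFit(
        kernels=kernels,
        train_ids=train_ids,
        sigma2_u=[float(s) for s in s2s],
        sigma2_e=float(res["s2_e"]),
        intercept=float(res["mu"]),
        alpha=np.asarray(alpha, dtype=float),
        blups=blups,
        fitted=fitted,
        residuals=residuals,
        reml_converged=bool(res["converged"]),
        rll=float(res["rll"]),
    )


def predict_unobserved(fit: KernelModelFit, test_ids) -> pd.Series:
    """Predicted trait values for trees absent from the training phenotypes:
    ``mu + sum_k s2_k K_k[test, train] alpha``."""
    test_ids = list(test_ids)
    pred = np.full(len(test_ids), fit.intercept)
    for s2, k in zip(fit.sigma2_u, fit.kernels):
        if s2 > 0:
            pred = pred + s2 * (k.block(test_ids, fit.train_ids) @ fit.alpha)
    return pd.Series(pred, index=test_ids)


def _build_model_kernels(model: str, Xs, trees_frame, h, rho) -> list[KernelMatrix]:
    base = gb_kernel(Xs) if model.startswith("GB") else gk_kernel(Xs, h=h)
    out = [base]
    if model.endswith("+P"):
        tf = trees_frame.set_index("tree_id").loc[list(Xs.index)].reset_index()
        out.append(pedigree_kernel(tf, rho=rho))
    return out


def cross_validate(data, month: str, trait: str, config: CVConfig) -> CVResult:
    """Repeated random 80/20 cross-validation for the requested models.

    ``data`` is a :class:`~phenosel.synthdata.SimulatedDataset` (or any object
    with ``observations`` and ``trees_frame()``).  Splits are a pure function
    of ``(config.seed, sorted id list)`` and are shared across models within a
    rep.  Reps whose test set is degenerate (< 3 observations or constant)
    are skipped and counted.
    """
    obs = data.observations
    trees_frame = data.trees_frame()
    col = TRAIT_COLUMNS.get(trait, trait)
    sl = obs.loc[obs["month"] == month].sort_values("tree_id")
    if len(sl) < 20:
        raise ValueError(f"need >= 20 phenotyped trees in {month!r}, got {len(sl)}")
    y_all = pd.Series(sl[col].to_numpy(dtype=float), index=sl["tree_id"].to_numpy())
    y_all = y_all.dropna()
    ids = sorted(y_all.index)
    y_all = y_all.loc[ids]

    feats = build_feature_matrix(obs, month).loc[ids]
    Xs = standardize(feats)
    model_kernels = {
        m: _build_model_kernels(m, Xs, trees_frame, config.h, config.rho)
        for m in config.models
    }
    fam_of = trees_frame.set_index("tree_id")["family"].to_dict()
    families = sorted({fam_of[t] for t in ids})

    rng = np.random.default_rng(config.seed)
    rows = []
    skipped = {m: 0 for m in config.models}
    for rep in range(config.n_reps):
        if config.split == "tree":
            perm = rng.permutation(len(ids))
            n_train = int(round(config.train_fraction * len(ids)))
            train = [ids[i] for i in perm[:n_train]]
            test = [ids[i] for i in perm[n_train:]]
        else:
            perm = rng.permutation(len(families))
            n_train = int(round(config.train_fraction * len(families)))
            keep = {families[i] for i in perm[:n_train]}
            train = [t for t in ids if fam_of[t] in keep]
            test = [t for t in ids if fam_of[t] not in keep]
        y_test = y_all.loc[test]
        degenerate = len(y_test) < 3 or float(np.std(y_test)) == 0
        for m in config.models:
            if degenerate:
                warnings.warn(
                    f"rep {rep}: degenerate test set; skipped for {m}", RuntimeWarning
                )
                skipped[m] += 1
                continue
            fit = fit_kernel_blup(y_all.loc[train], model_kernels[m])
            pred = predict_unobserved(fit, test)
            if float(np.std(pred)) == 0:
                r = 0.0  # no usable signal in the predictions
            else:
                r = float(np.corrcoef(y_test.to_numpy(), pred.to_numpy())[0, 1])
            rows.append(
                {"month": month, "trait": trait, "model": m, "rep": rep, "r": r}
            )
    per_rep = pd.DataFrame(rows, columns=["month", "trait", "model", "rep", "r"])
    summaries = []
    for m in config.models:
        rs = per_rep.loc[per_rep["model"] == m, "r"]
        summaries.append(
            CVSummary(
                month=month,
                trait=trait,
                model=m,
                mean_r=float(rs.mean()) if len(rs) else float("nan"),
                sd_r=float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
                n_reps=int(len(rs)),
                n_skipped=skipped[m],
            )
        )
    return CVResult(summaries=summaries, per_rep=per_rep)
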
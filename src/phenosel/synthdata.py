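"""Synthetic open-pollinated progeny trial with known genetic architecture.

Emulates a two-site lattice trial of single-tree plots: every block contains
exactly one tree of every family, a fixed fraction of trees dies, and the
survivors are observed monthly for five band reflectances plus height and
crown area.  All generating effects (family, block, tree-level residual) are
retained in ``SimulatedDataset.truth`` so downstream estimators have an exact
parameter-recovery surface.

Generating model per trait and month::

    y = level(month) + block + family + residual_perm + residual_month

Family effects for (height, crown_area, latent) are drawn jointly under the
configured genetic correlation matrix; block and permanent-residual effects
share a single environmental correlation.  The latent channel loads onto all
five bands, giving spectra a genetic (and environmental) covariance with
growth without modelling a physiological mechanism.

Height uses a purely permanent residual by default, so within a tree it is
exactly the non-decreasing cumulative growth curve shifted by a constant.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAITS = ("height", "crown_area", "latent")

DEFAULT_MONTHS = (
    "Jan",
    "Mar",
    "Apr",
    "May",
    "Jun",
    "Jul",
    "Aug",
    "Sep",
    "Oct",
    "Nov",
    "Dec",
)

# Multiplicative monthly growth increments: fast April-September, near-zero
# in winter.  Keys beyond the configured month list are ignored.
DEFAULT_GROWTH_PROFILE = {
    "Jan": 0.005,
    "Feb": 0.005,
    "Mar": 0.01,
    "Apr": 0.06,
    "May": 0.08,
    "Jun": 0.09,
    "Jul": 0.09,
    "Aug": 0.08,
    "Sep": 0.06,
    "Oct": 0.02,
    "Nov": 0.01,
    "Dec": 0.005,
}

_DEFAULT_RG = (
    (1.0, 0.7, 0.8),
    (0.7, 1.0, 0.7),
    (0.8, 0.7, 1.0),
)

# Band baseline reflectances, seasonal amplitudes and loadings on the latent
# family-vigor channel.  Values are plausible conifer-canopy magnitudes; only
# their relative sizes matter to the estimators.
BAND_BASELINE = {"blue": 0.04, "green": 0.08, "red": 0.05, "rededge": 0.25, "nir": 0.45}
BAND_SEASONAL = {"blue": -0.005, "green": 0.01, "red": -0.01, "rededge": 0.03, "nir": 0.06}
BAND_LOADING = {"blue": -0.010, "green": 0.020, "red": -0.030, "rededge": 0.040, "nir": 0.080}
BAND_NOISE_SD = {"blue": 0.004, "green": 0.006, "red": 0.006, "rededge": 0.012, "nir": 0.015}


@dataclass
class TrialConfig:
    """Parameters of the simulated trial.

    ``sigma2_family/block/residual`` are per-trait variances for the keys in
    :data:`TRAITS`; ``rg_matrix`` is the 3x3 genetic (family-effect)
    correlation matrix in the same trait order; ``env_corr`` is the common
    correlation applied to block and permanent-residual effects across
    traits.  ``month_noise_fraction`` splits the residual variance into a
    permanent tree component and independent monthly noise (height defaults
    to fully permanent so its growth curve stays monotone).
    """

    n_sites: int = 2
    n_blocks_per_site: int = 20
    n_families: int = 20
    trees_per_block: int = 20
    mortality_rate: float = 0.30
    months: tuple[str, ...] = DEFAULT_MONTHS
    sigma2_family: dict[str, float] = field(
        default_factory=lambda: {"height": 0.12, "crown_area": 0.10, "latent": 0.12}
    )
    sigma2_block: dict[str, float] = field(
        default_factory=lambda: {"height": 0.08, "crown_area": 0.10, "latent": 0.08}
    )
    sigma2_residual: dict[str, float] = field(
        default_factory=lambda: {"height": 0.80, "crown_area": 0.80, "latent": 0.80}
    )
    rg_matrix: tuple = _DEFAULT_RG
    env_corr: float = 0.5
    month_noise_fraction: dict[str, float] = field(
        default_factory=lambda: {"height": 0.0, "crown_area": 0.10, "latent": 0.0}
    )
    growth_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_PROFILE)
    )
    base_height: float = 6.0
    base_crown_area: float = 4.0
    site_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.mortality_rate < 1):
            raise ValueError(
                f"mortality_rate must be in [0, 1), got {self.mortality_rate}"
            )
        if self.n_families != self.trees_per_block:
            raise ValueError(
                "single-tree plot design requires n_families == trees_per_block "
                f"(got {self.n_families} != {self.trees_per_block})"
            )
        for name in ("n_sites", "n_blocks_per_site", "n_families"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for d in (self.sigma2_family, self.sigma2_block, self.sigma2_residual):
            for t in TRAITS:
                if d[t] < 0:
                    raise ValueError(f"variance for trait {t!r} must be >= 0")
        R = np.asarray(self.rg_matrix, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("rg_matrix must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("rg_matrix must have a unit diagonal")
        w = np.linalg.eigvalsh(R)
        if w[0] < -1e-10:
            raise ValueError(
                f"rg_matrix is not positive semidefinite: smallest eigenvalue {w[0]:.3e}"
            )
        for t in TRAITS:
            if not (0 <= self.month_noise_fraction[t] <= 1):
                raise ValueError("month_noise_fraction must be in [0, 1]")
        for m, g in self.growth_profile.items():
            if g < 0:
                raise ValueError(f"growth increment for {m!r} must be >= 0")

    @property
    def n_trees(self) -> int:
        return self.n_sites * self.n_blocks_per_site * self.n_families

    @property
    def n_dead(self) -> int:
        return math.floor(self.mortality_rate * self.n_trees)

    @property
    def n_alive(self) -> int:
        return self.n_trees - self.n_dead

    def plugin_h2(self, trait: str, coefficient: float = 2.5) -> float:
        """Heritability implied by the configured (true) variances."""
        vf = self.sigma2_family[trait]
        tot = vf + self.sigma2_block[trait] + self.sigma2_residual[trait]
        return coefficient * vf / tot if tot > 0 else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rg_matrix"] = np.asarray(self.rg_matrix, dtype=float).tolist()
        d["months"] = list(self.months)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "months" in d:
            d["months"] = tuple(d["months"])
        if "rg_matrix" in d:
            d["rg_matrix"] = tuple(tuple(row) for row in d["rg_matrix"])
        return cls(**d)


@dataclass(frozen=True)
class TreeRecord:
    tree_id: str
    site_id: str
    block_id: str
    family_id: str
    alive: bool


@dataclass
class SimulatedDataset:
    """Trees, their monthly observations, and the hidden generating truth."""

    trees: list[TreeRecord]
    observations: pd.DataFrame
    truth: dict

    @property
    def config(self) -> TrialConfig:
        return self.truth["config"]

    def trees_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": [t.tree_id for t in self.trees],
                "site": [t.site_id for t in self.trees],
                "block": [t.block_id for t in self.trees],
                "family": [t.family_id for t in self.trees],
                "alive": [int(t.alive) for t in self.trees],
            }
        )

    def analysis_frame(self) -> pd.DataFrame:
        """Observations joined with site/block/family labels."""
        return self.observations.merge(self.trees_frame(), on="tree_id", how="left")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # One master seed; deterministic child streams so stages can be re-run
    # independently.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_trial(config: TrialConfig) -> list[TreeRecord]:
    """Lay out the full crossed design and apply exact-count mortality.

    Exactly ``floor(mortality_rate * n_trees)`` trees are marked dead, chosen
    uniformly at random under the configured seed.
    """
    config.validate()
    rng_mort = _child_rngs(config.seed, 3)[0]
    trees: list[TreeRecord] = []
    for s in range(config.n_sites):
        site = f"S{s + 1}"
        for b in range(config.n_blocks_per_site):
            block = f"{site}_B{b + 1:02d}"
            for f in range(config.n_families):
                fam = f"F{f + 1:02d}"
                trees.append(TreeRecord(f"{block}_{fam}", site, block, fam, True))
    dead_idx = rng_mort.choice(len(trees), size=config.n_dead, replace=False)
    dead = set(dead_idx.tolist())
    return [
        dataclasses.replace(t, alive=(i not in dead)) for i, t in enumerate(trees)
    ]


def _correlated_effects(
    n: int, variances: np.ndarray, corr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw n rows of zero-mean effects with the given per-trait variances and
    correlation matrix (PSD; degenerate directions handled via eigen square
    root)."""
    sd = np.sqrt(variances)
    cov = corr * np.outer(sd, sd)
    w, U = np.linalg.eigh(cov)
    if w[0] < -1e-10:
        raise ValueError(
            f"effect correlation matrix not PSD: smallest eigenvalue {w[0]:.3e}"
        )
    L = U * np.sqrt(np.clip(w, 0, None))
    return rng.standard_normal((n, len(variances))) @ L.T


def draw_family_effects(
    n_families: int, config: TrialConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Joint family effects for (height, crown_area, latent) under the
    configured variances and genetic correlation matrix."""
    if rng is None:
        rng = _child_rngs(config.seed, 3)[1]
    R = np.asarray(config.rg_matrix, dtype=float)
    v = np.array([config.sigma2_family[t] for t in TRAITS])
    eff = _correlated_effects(n_families, v, R, rng)
    fams = [f"F{i + 1:02d}" for i in range(n_families)]
    return pd.DataFrame(eff, index=pd.Index(fams, name="family"), columns=TRAITS)


def _env_corr_matrix(c: float) -> np.ndarray:
    R = np.full((3, 3), c)
    np.fill_diagonal(R, 1.0)
    return R


def _cumulative_levels(config: TrialConfig) -> np.ndarray:
    """Cumulative multiplicative growth factor per configured month."""
    fac, out = 1.0, []
    for m in config.months:
        fac *= 1.0 + config.growth_profile.get(m, 0.0)
        out.append(fac)
    return np.asarray(out)


def simulate_observations(
    trees: list[TreeRecord], config: TrialConfig
) -> SimulatedDataset:
    """Simulate the monthly long table for all alive trees.

    Effects are drawn once (family, block, permanent residual) and shifted by
    the cumulative growth curve, plus optional independent monthly noise, so
    each month slice follows ``mean + block + family + residual`` with the
    configured variances.
    """
    config.validate()
    rngs = _child_rngs(config.seed, 3)
    rng = rngs[2]

    fam_ids = sorted({t.family_id for t in trees})
    block_ids = sorted({t.block_id for t in trees})
    fam_eff = draw_family_effects(len(fam_ids), config, rngs[1])
    fam_eff.index = pd.Index(fam_ids, name="family")

    Renv = _env_corr_matrix(config.env_corr)
    vb = np.array([config.sigma2_block[t] for t in TRAITS])
    blk = _correlated_effects(len(block_ids), vb, Renv, rng)
    blk_eff = pd.DataFrame(blk, index=pd.Index(block_ids, name="block"), columns=TRAITS)

    alive = [t for t in trees if t.alive]
    n = len(alive)
    wfrac = np.array([config.month_noise_fraction[t] for t in TRAITS])
    ve = np.array([config.sigma2_residual[t] for t in TRAITS])
    perm = _correlated_effects(n, ve * (1 - wfrac), Renv, rng)
    tree_resid = pd.DataFrame(
        perm,
        index=pd.Index([t.tree_id for t in alive], name="tree_id"),
        columns=TRAITS,
    )

    fam_idx = np.array([fam_ids.index(t.family_id) for t in alive])
    blk_idx = np.array([block_ids.index(t.block_id) for t in alive])
    site_num = np.array([int(t.site_id[1:]) - 1 for t in alive], dtype=float)

    # per-tree static deviation per trait (n x 3)
    dev = fam_eff.to_numpy()[fam_idx] + blk_eff.to_numpy()[blk_idx] + perm
    dev[:, 0] += config.site_offset * site_num  # site mean offset, default 0
    dev[:, 1] += config.site_offset * site_num

    levels = _cumulative_levels(config)
    gmax = max(config.growth_profile.get(m, 0.0) for m in config.months)
    season = np.array(
        [config.growth_profile.get(m, 0.0) / gmax if gmax > 0 else 0.0 for m in config.months]
    )

    n_m = len(config.months)
    rows: dict[str, np.ndarray] = {}
    tree_ids = np.array([t.tree_id for t in alive])
    rows["tree_id"] = np.repeat(tree_ids, n_m)
    rows["month"] = np.tile(np.array(config.months, dtype=object), n)

    month_noise = rng.standard_normal((n, n_m, 3)) * np.sqrt(ve * wfrac)

    height = (
        config.base_height * levels[None, :]
        + dev[:, [0]]
        + month_noise[:, :, 0]
    )
    height = np.maximum(height, 0.01)
    height = np.maximum.accumulate(height, axis=1)  # enforce growth monotonicity
    crown = (
        config.base_crown_area * levels[None, :]
        + dev[:, [1]]
        + month_noise[:, :, 1]
    )
    crown = np.maximum(crown, 0.01)
    latent = dev[:, [2]] + month_noise[:, :, 2]  # (n, n_m)

    for band in ("blue", "green", "red", "rededge", "nir"):
        vals = (
            BAND_BASELINE[band]
            + BAND_SEASONAL[band] * season[None, :]
            + BAND_LOADING[band] * latent
            + rng.standard_normal((n, n_m)) * BAND_NOISE_SD[band]
        )
        rows[band] = np.clip(vals, 0.0, 1.0).ravel()
    rows["height_m"] = height.ravel()
    rows["crown_area_m2"] = crown.ravel()

    observations = pd.DataFrame(rows)[
        [
            "tree_id",
            "month",
            "blue",
            "green",
            "red",
            "rededge",
            "nir",
            "height_m",
            "crown_area_m2",
        ]
    ]
    truth = {
        "config": config,
        "family_effects": fam_eff,
        "block_effects": blk_eff,
        "tree_residuals": tree_resid,
    }
    return SimulatedDataset(trees=list(trees), observations=observations, truth=truth)


def simulate_trial(config: TrialConfig) -> SimulatedDataset:
    """Convenience wrapper: layout + mortality + observations."""
    return simulate_observations(generate_trial(config), config)


def export_dataset(data: SimulatedDataset, path: str) -> None:
    """Write trees.csv, observations.csv and truth.json under ``path``."""
    os.makedirs(path, exist_ok=True)
    data.trees_frame().to_csv(os.path.join(path, "trees.csv"), index=False)
    data.observations.to_csv(
        os.path.join(path, "observations.csv"), index=False, float_format="%.12g"
    )
    truth = {
        "config": data.config.to_dict(),
        "family_effects": data.truth["family_effects"].reset_index().to_dict("list"),
        "block_effects": data.truth["block_effects"].reset_index().to_dict("list"),
        "tree_residuals": data.truth["tree_residuals"].reset_index().to_dict("list"),
    }
    with open(os.path.join(path, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)


def read_dataset(path: str) -> SimulatedDataset:
    """Round-trip reader for :func:`export_dataset` output."""
    trees_df = pd.read_csv(os.path.join(path, "trees.csv"))
    observations = pd.read_csv(os.path.join(path, "observations.csv"))
    trees = [
        TreeRecord(
            str(r.tree_id), str(r.site), str(r.block), str(r.family), bool(r.alive)
        )
        for r in trees_df.itertuples()
    ]
    truth: dict = {}
    tpath = os.path.join(path, "truth.json")
    if os.path.exists(tpath):
        with open(tpath, encoding="utf-8") as fh:
            raw = json.load(fh)
        truth["config"] = TrialConfig.from_dict(raw["config"])
        for key, idx in (
            ("family_effects", "family"),
            ("block_effects", "block"),
            ("tree_residuals", "tree_id"),
        ):
            truth[key] = pd.DataFrame(raw[key]).set_index(idx)
    return SimulatedDataset(trees=trees, observations=observations, truth=truth)
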
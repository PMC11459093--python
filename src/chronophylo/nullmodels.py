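"""Standardized-effect phylogenetic structure: NRI and NTI.

The observed MPD (or MNTD) of a community is compared with a richness-
preserving randomization null: each of ``n_reps`` replicates (999 by default)
draws the same number of species uniformly without replacement from the
species pool — by default every tip of the regional phylogeny — and the
standardized score is

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

so positive values indicate phylogenetic aggregation (closer relatives than
expected: environmental filtering), negative values dispersion (competitive
exclusion), and zero a stochastic structure.

The null standard deviation uses the sample (n-1) estimator of the replicate
distribution.  Degenerate nulls (sd below 1e-12, e.g. when the community
exhausts the pool) yield a ``nan`` score with a flag rather than a silent 0.

Randomness is reproducible: per-plot RNG streams are derived from the master
seed and a stable hash of the plot id, so results do not depend on plot
order.
"""

from __future__ import annotations

import logging
import zlib
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import mntd_from_matrix, mpd_from_matrix
from .trees import Phylogeny

__all__ = [
    "NullModelConfig",
    "SESResult",
    "null_metric_distribution",
    "nri",
    "nti",
    "ses_table",
]

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


@dataclass
class NullModelConfig:
    """Settings for the randomization null.

    ``pool=None`` means "all tips of the (pruned) regional phylogeny".
    ``mode`` chooses between uniform subset draws from the pool
    (``"pool"``, the default) and drawing the leading block of a pool
    permutation (``"shuffle"``, a taxa-label shuffle; identical in
    distribution for presence-based metrics).
    """

    n_reps: int = 999
    pool: tuple[str, ...] | None = None
    rng_seed: int | None = None
    mode: str = "pool"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.mode not in ("pool", "shuffle"):
            raise ValueError(f"unknown null mode {self.mode!r}")


@dataclass
class SESResult:
    """Observed metric, null moments, and the standardized score."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    score: float
    n_reps: int
    plot_id: object | None = None
    level: str | None = None

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.score))


def plot_rng(master_seed: int | None, plot_key: object) -> np.random.Generator:
    """Deterministic per-plot RNG independent of plot iteration order."""
    h = zlib.crc32(str(plot_key).encode("utf8"))
    ss = np.random.SeedSequence((0 if master_seed is None else master_seed, h))
    return np.random.default_rng(ss)


def _draw_indices(
    pool_idx: np.ndarray, k: int, n_reps: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """(n_reps, k) integer array of uniform without-replacement draws."""
    n = pool_idx.size
    if mode == "shuffle":
        draws = np.empty((n_reps, k), dtype=np.intp)
        for r in range(n_reps):
            draws[r] = rng.permutation(pool_idx)[:k]
        return draws
    # uniform k-subsets: k smallest of n iid uniforms per replicate
    u = rng.random((n_reps, n))
    part = np.argpartition(u, k - 1, axis=1)[:, :k]
    return pool_idx[part]


def _metric_many(D: np.ndarray, draws: np.ndarray, metric: str) -> np.ndarray:
    """Evaluate MPD or MNTD for each row of tip indices in ``draws``."""
    sub = D[draws[:, :, None], draws[:, None, :]]
    k = draws.shape[1]
    if metric == "mpd":
        iu = np.triu_indices(k, 1)
        return sub[:, iu[0], iu[1]].mean(axis=1)
    if metric == "mntd":
        r = np.arange(k)
        sub[:, r, r] = np.inf
        return sub.min(axis=2).mean(axis=1)
    raise ValueError(f"unknown metric {metric!r}")


def null_metric_distribution(
    tree: Phylogeny,
    metric: str,
    k: int,
    config: NullModelConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample of ``n_reps`` null metric values at richness ``k``.

    Each replicate draws ``k`` distinct species uniformly from the pool and
    evaluates the metric on the patristic matrix.
    """
    pool = config.pool if config.pool is not None else tree.tip_labels
    pool_idx = tree.indices_of(pool)
    if k < 2:
        raise ValueError("null distributions require richness k >= 2")
    if k > pool_idx.size:
        raise ValueError(f"richness {k} exceeds pool size {pool_idx.size}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    draws = _draw_indices(pool_idx, k, config.n_reps, rng, config.mode)
    return _metric_many(tree.patristic_matrix, draws, metric)


def _ses(
    tree: Phylogeny,
    present: Sequence[str],
    config: NullModelConfig,
    metric: str,
    score_name: str,
    rng: np.random.Generator | None,
    plot_id=None,
    level=None,
) -> SESResult:
    present = list(dict.fromkeys(present))
    k = len(present)
    if k < 2:
        raise ValueError(f"{score_name} requires at least 2 species (got {k})")
    idx = tree.indices_of(present)
    D = tree.patristic_matrix
    sub = D[np.ix_(idx, idx)]
    observed = mpd_from_matrix(sub) if metric == "mpd" else mntd_from_matrix(sub)
    null = null_metric_distribution(tree, metric, k, config, rng=rng)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if sd < _SD_FLOOR:
        logger.warning(
            "%s null distribution degenerate (sd=%.3g) for plot %s; score undefined",
            score_name, sd, plot_id,
        )
        score = float("nan")
    else:
        score = -(observed - mean) / sd
    return SESResult(
        metric=metric.upper(),
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        score=score,
        n_reps=config.n_reps,
        plot_id=plot_id,
        level=level,
    )


def nri(
    tree: Phylogeny,
    present: Sequence[str],
    config: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
    **kw,
) -> SESResult:
    """Net relatedness index of a community (standardized MPD, negated)."""
    return _ses(tree, present, config or NullModelConfig(), "mpd", "NRI", rng, **kw)


def nti(
    tree: Phylogeny,
    present: Sequence[str],
    config: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
    **kw,
) -> SESResult:
    """Net nearest-taxon index of a community (standardized MNTD, negated)."""
    return _ses(tree, present, config or NullModelConfig(), "mntd", "NTI", rng, **kw)


def ses_table(
    tree: Phylogeny,
    survey: pd.DataFrame,
    levels: Iterable[str] = ("total", "herb", "woody"),
    config: NullModelConfig | None = None,
    pool_per_level: bool = True,
) -> pd.DataFrame:
    """NRI and NTI for every plot and analysis level.

    For ``pool_per_level`` (default), the total-community null draws from the
    whole phylogeny while herb and woody nulls draw from the corresponding
    life-form subpool observed anywhere in the survey.  Plots with fewer than
    two species at a level are skipped with a warning.
    """
    config = config or NullModelConfig()
    level_pools: dict[str, tuple[str, ...]] = {}
    for level in levels:
        if config.pool is not None:
            level_pools[level] = tuple(config.pool)
        elif level == "total" or not pool_per_level:
            level_pools[level] = tree.tip_labels
        else:
            sp = survey.loc[survey["level"] == level, "species"].unique()
            level_pools[level] = tuple(s for s in tree.tip_labels if s in set(sp))
    rows = []
    for plot, sub in survey.groupby("plot_id", sort=True):
        sub = sub[sub["abundance"] > 0]
        stage = sub["stage_years"].iloc[0] if "stage_years" in sub.columns else None
        for level in levels:
            part = sub if level == "total" else sub[sub["level"] == level]
            species = sorted(part["species"].unique())
            if len(species) < 2:
                if species:
                    logger.warning(
                        "plot %s level %s has %d species; NRI/NTI skipped",
                        plot, level, len(species),
                    )
                continue
            cfg = NullModelConfig(
                n_reps=config.n_reps,
                pool=level_pools[level],
                rng_seed=config.rng_seed,
                mode=config.mode,
            )
            rng = plot_rng(config.rng_seed, (plot, level))
            for fn, name in ((nri, "NRI"), (nti, "NTI")):
                res = fn(tree, species, cfg, rng=rng, plot_id=plot, level=level)
                rows.append(
                    {
                        "plot_id": plot,
                        "stage_years": stage,
                        "level": level,
                        "metric": name,
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "score": res.score,
                        "n_reps": res.n_reps,
                        "seed": config.rng_seed,
                    }
                )
    return pd.DataFrame(rows)
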
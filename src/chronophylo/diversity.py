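"""Community phylogenetic diversity metrics.

Implements the five per-community quantities used along the chronosequence:

* Faith's PD — total branch length of the spanning subtree (root-inclusive by
  default).
* PSV — phylogenetic species variability, ``(k*tr(C) - sum(C)) / (k*(k-1))``
  where ``C`` is the phylogenetic correlation matrix of the present species.
* PSR — phylogenetic species richness, ``k * PSV``.
* PSE — phylogenetic species evenness, the abundance-weighted analogue of PSV
  (1 on a star phylogeny with equal abundances).
* MPD / MNTD — mean pairwise and mean nearest-taxon patristic distance
  (presence-based by default; abundance weighting available).

Metrics undefined for a community (fewer than two species) return ``nan``
rather than raising, so tables of plots with occasional monocultures can be
built in one pass; callers that need hard failures can check ``numpy.isnan``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = [
    "faith_pd",
    "psv",
    "psr",
    "pse",
    "mpd",
    "mntd",
    "mpd_from_matrix",
    "mntd_from_matrix",
    "community_diversity",
]

logger = logging.getLogger(__name__)


def faith_pd(tree: Phylogeny, present: Iterable[str], include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of the species in ``present``.

    The cumulative branch length connecting the species; by default the
    spanning subtree includes the path up to the root, so a single species
    contributes its root-to-tip distance.
    """
    present = list(present)
    if not present:
        raise ValueError("faith_pd requires at least one species")
    return tree.pd_edges(present, include_root=include_root)


def _correlation_submatrix(tree: Phylogeny, present: Iterable[str]) -> np.ndarray:
    idx = tree.indices_of(present)
    return tree.correlation_matrix[np.ix_(idx, idx)]


def psv(tree: Phylogeny, present: Iterable[str]) -> float:
    """Phylogenetic species variability (1 = star phylogeny, unrelated species)."""
    present = list(present)
    k = len(present)
    if k < 2:
        logger.warning("PSV undefined for %d species; returning nan", k)
        return float("nan")
    C = _correlation_submatrix(tree, present)
    return float((k * np.trace(C) - C.sum()) / (k * (k - 1)))


def psr(tree: Phylogeny, present: Iterable[str]) -> float:
    """Phylogenetic species richness: species count discounted by relatedness."""
    present = list(present)
    return len(present) * psv(tree, present)


def pse(tree: Phylogeny, abundances: Mapping[str, float]) -> float:
    """Phylogenetic species evenness.

    Abundance-weighted PSV: with correlation matrix ``C``, abundance vector
    ``m`` (total ``N``, ``k`` species, mean ``N/k``),

        PSE = (N * sum_i m_i C_ii - m' C m) / (N**2 - N * N/k)

    which attains 1 exactly for a star phylogeny with equal abundances and is
    invariant under scaling all abundances by a common factor.
    """
    items = [(sp, float(m)) for sp, m in abundances.items() if m > 0]
    k = len(items)
    if k < 2:
        logger.warning("PSE undefined for %d species; returning nan", k)
        return float("nan")
    species = [sp for sp, _ in items]
    m = np.array([a for _, a in items], dtype=float)
    N = m.sum()
    C = _correlation_submatrix(tree, species)
    num = N * float(m @ np.diag(C)) - float(m @ C @ m)
    den = N * N - N * (N / k)
    return float(num / den)


def _pair_weights(weights: np.ndarray) -> np.ndarray:
    W = np.outer(weights, weights)
    np.fill_diagonal(W, 0.0)
    return W


def mpd_from_matrix(D: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean pairwise distance from a k x k patristic submatrix (nan if k < 2)."""
    k = D.shape[0]
    if k < 2:
        return float("nan")
    if weights is None:
        iu = np.triu_indices(k, 1)
        return float(D[iu].mean())
    W = _pair_weights(np.asarray(weights, dtype=float))
    return float((W * D).sum() / W.sum())


def mntd_from_matrix(D: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean nearest-taxon distance from a k x k patristic submatrix."""
    k = D.shape[0]
    if k < 2:
        return float("nan")
    M = D.astype(float).copy()
    np.fill_diagonal(M, np.inf)
    nearest = M.min(axis=1)
    if weights is None:
        return float(nearest.mean())
    w = np.asarray(weights, dtype=float)
    return float((w * nearest).sum() / w.sum())


def mpd(tree: Phylogeny, present: Iterable[str], weights: Mapping[str, float] | None = None) -> float:
    """Mean pairwise patristic distance among the present species.

    Presence-based (unweighted) by default; pass per-species ``weights`` for
    the abundance-weighted variant.
    """
    present = list(present)
    idx = tree.indices_of(present)
    D = tree.patristic_matrix[np.ix_(idx, idx)]
    w = None if weights is None else np.array([weights[s] for s in present], float)
    return mpd_from_matrix(D, w)


def mntd(tree: Phylogeny, present: Iterable[str], weights: Mapping[str, float] | None = None) -> float:
    """Mean distance from each present species to its nearest present relative."""
    present = list(present)
    idx = tree.indices_of(present)
    D = tree.patristic_matrix[np.ix_(idx, idx)]
    w = None if weights is None else np.array([weights[s] for s in present], float)
    return mntd_from_matrix(D, w)


def community_diversity(
    tree: Phylogeny,
    survey: pd.DataFrame,
    levels: Iterable[str] = ("total", "herb", "woody"),
    include_root: bool = True,
) -> pd.DataFrame:
    """Per-plot, per-level diversity table.

    ``survey`` is tidy: one row per (plot, species) with columns ``plot_id``,
    ``stage_years``, ``species``, ``abundance``, ``level`` (herb/woody).
    Returns one row per plot x level with PD, PSV, PSR, PSE, MPD, MNTD,
    richness ``k`` and total abundance ``N``; metrics that need two or more
    species are ``nan`` for monocultures.
    """
    required = {"plot_id", "species", "abundance", "level"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    rows = []
    has_stage = "stage_years" in survey.columns
    group_cols = ["plot_id", "stage_years"] if has_stage else ["plot_id"]
    for key, sub in survey.groupby(group_cols, sort=True):
        plot = key[0] if isinstance(key, tuple) else key
        stage = key[1] if has_stage and isinstance(key, tuple) else None
        for level in levels:
            part = sub if level == "total" else sub[sub["level"] == level]
            part = part[part["abundance"] > 0]
            if part.empty:
                continue
            ab = part.groupby("species")["abundance"].sum()
            species = list(ab.index)
            k = len(species)
            row = {
                "plot_id": plot,
                "level": level,
                "k": k,
                "N": float(ab.sum()),
                "PD": faith_pd(tree, species, include_root=include_root),
                "PSV": psv(tree, species),
                "MPD": mpd(tree, species),
                "MNTD": mntd(tree, species),
                "PSE": pse(tree, ab.to_dict()),
            }
            row["PSR"] = k * row["PSV"]
            if has_stage:
                row["stage_years"] = stage
            rows.append(row)
    cols = ["plot_id", "level", "k", "N", "PD", "PSV", "PSR", "PSE", "MPD", "MNTD"]
    if has_stage:
        cols.insert(1, "stage_years")
    out = pd.DataFrame(rows)
    return out[cols] if not out.empty else pd.DataFrame(columns=cols)
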
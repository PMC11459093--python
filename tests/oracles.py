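"""Brute-force reference implementations used only by the tests.

These deliberately take a different route from the package: dendropy's own
MRCA/age arithmetic and explicit O(k^2) pair loops, so agreement is a real
cross-check rather than the same code twice.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from chronophylo.trees import Phylogeny


def _dendropy_copy(tree: Phylogeny) -> dendropy.Tree:
    t = dendropy.Tree.get(data=tree.as_newick(), schema="newick",
                          preserve_underscores=True)
    t.is_rooted = True  # keep the root bifurcation when encoding bipartitions
    return t


def pd_bruteforce(tree: Phylogeny, present, include_root: bool = True) -> float:
    """Faith's PD by scanning every edge for presence beneath it."""
    t = _dendropy_copy(tree)
    present = set(present)
    total = 0.0
    for edge in t.preorder_edge_iter():
        if edge.length is None:
            continue
        below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        if below & present:
            if include_root or not (below >= present):
                total += edge.length
    return total


def patristic_bruteforce(tree: Phylogeny) -> dict[tuple[str, str], float]:
    t = _dendropy_copy(tree)
    pdm = t.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(t.taxon_namespace)
    for a, b in itertools.combinations(taxa, 2):
        d = pdm.patristic_distance(a, b)
        out[(a.label, b.label)] = d
        out[(b.label, a.label)] = d
    for a in taxa:
        out[(a.label, a.label)] = 0.0
    return out


def mpd_bruteforce(dists, subset) -> float:
    subset = list(subset)
    pairs = list(itertools.combinations(subset, 2))
    return float(np.mean([dists[p] for p in pairs]))


def mntd_bruteforce(dists, subset) -> float:
    subset = list(subset)
    mins = [
        min(dists[(a, b)] for b in subset if b != a)
        for a in subset
    ]
    return float(np.mean(mins))


def psv_bruteforce(tree: Phylogeny, subset) -> float:
    """PSV from dendropy MRCA depths (root-to-MRCA shared branch length)."""
    t = _dendropy_copy(tree)
    t.encode_bipartitions()
    labels = list(subset)
    depth = {}
    root_dist = {}
    for a in labels:
        node = t.find_node_with_taxon_label(a)
        root_dist[a] = node.distance_from_root()
    k = len(labels)
    C = np.eye(k)
    for i, a in enumerate(labels):
        for j in range(i + 1, k):
            b = labels[j]
            mrca = t.mrca(taxon_labels=[a, b])
            shared = mrca.distance_from_root()
            C[i, j] = C[j, i] = shared / np.sqrt(root_dist[a] * root_dist[b])
    return float((k * np.trace(C) - C.sum()) / (k * (k - 1)))


def null_mpd_exhaustive(tree: Phylogeny, pool, k: int, metric: str = "mpd"):
    """Exact null mean and population sd by enumerating every k-subset."""
    dists = patristic_bruteforce(tree)
    vals = []
    fn = mpd_bruteforce if metric == "mpd" else mntd_bruteforce
    for subset in itertools.combinations(pool, k):
        vals.append(fn(dists, subset))
    v = np.asarray(vals)
    return float(v.mean()), float(v.std(ddof=0)), v


def se_of_sample_sd(values: np.ndarray, n: int) -> float:
    """Standard error of the sd of n iid draws from this exact distribution.

    Delta method with the distribution's true kurtosis: Var(s) ~ (kappa-1)
    sigma^2 / (4n); reduces to sigma/sqrt(2n) for normal samples.
    """
    mu = values.mean()
    sigma2 = values.var(ddof=0)
    kappa = np.mean((values - mu) ** 4) / sigma2**2
    return float(np.sqrt(max(kappa - 1.0, 1e-12) * sigma2 / (4.0 * n)))
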
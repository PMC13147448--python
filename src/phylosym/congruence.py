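"""Phylosymbiosis signal detection.

Three detectors of host-phylogeny/microbiota congruence:

* the Mantel test between a host patristic distance matrix and a microbial
  beta-diversity matrix, optionally batched over random species subsamples of
  uniform size so sites with different species counts are comparable;
* UPGMA dendrograms of the microbiota with Robinson-Foulds (RF) and Matching
  Cluster (MC) topological distances to the host tree, normalized to [0, 1]
  (0 = complete congruence, 1 = complete incongruence) and tested against a
  tip-label permutation null.

All tests are one-sided in the direction of congruence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix

from .trees import HostTree, tree_clusters


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _upper(d: np.ndarray) -> np.ndarray:
    return d[np.triu_indices(d.shape[0], k=1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance among distances; Mantel r undefined")
    return float((xc @ yc) / denom)


def mantel(a: DistanceMatrix, b: DistanceMatrix, n_permutations: int = 999,
           seed: int | None = None, alternative: str = "greater") -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same ids.

    r is the Pearson correlation of upper-triangle entries; p comes from
    jointly permuting the rows/columns of ``b``, one-sided by default
    (``greater``: congruence = positive correlation), with the +1 correction.
    Set ``n_permutations=0`` to skip the permutation test (p = nan).
    """
    if list(a.ids) != list(b.ids):
        if set(a.ids) != set(b.ids):
            raise ValueError("distance matrices have different id sets")
        b = b.filter(a.ids)
    n = len(a.ids)
    if n < 4:
        raise ValueError("need at least 4 ids for a Mantel test")
    x = _upper(a.data)
    bd = b.data
    r_obs = _pearson(x, _upper(bd))
    if n_permutations <= 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        r_p = _pearson(x, _upper(bd[np.ix_(p, p)]))
        if alternative == "greater":
            exceed += r_p >= r_obs
        elif alternative == "less":
            exceed += r_p <= r_obs
        elif alternative == "two-sided":
            exceed += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return r_obs, (1.0 + exceed) / (n_permutations + 1.0)


@dataclass
class MantelBatchResult:
    """Subsampled Mantel battery: one (r, p) per random species subsample."""

    r_values: np.ndarray
    p_values: np.ndarray
    subsample_size: int
    n_resamplings: int
    n_permutations: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < 0.05))


def subsampled_mantel(host_d: DistanceMatrix, micro_d: DistanceMatrix,
                      subsample_size: int, n_resamplings: int = 10_000,
                      n_permutations: int = 999,
                      seed: int | None = None) -> MantelBatchResult:
    """Mantel tests on repeated uniform subsamples of species.

    Species are drawn without replacement; each draw's aligned sub-matrices
    get an independent Mantel test.  Subsampling and permutation randomness
    come from independent sub-streams of ``seed``.
    """
    if set(host_d.ids) != set(micro_d.ids):
        raise ValueError("host and microbiota matrices cover different species")
    micro_d = micro_d.filter(host_d.ids)
    ids = np.array(host_d.ids)
    n = len(ids)
    k = subsample_size
    if k > n:
        raise ValueError(f"subsample size {k} exceeds available species count {n}")
    if k < 4:
        raise ValueError("subsample size must be >= 4")
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    perm_seeds = ss.spawn(n_resamplings + 1)[1:]
    hd, md = host_d.data, micro_d.data
    rs, ps = np.empty(n_resamplings), np.empty(n_resamplings)
    for s in range(n_resamplings):
        idx = np.sort(draw_rng.choice(n, size=k, replace=False)) if k < n else np.arange(n)
        sub_h = DistanceMatrix(hd[np.ix_(idx, idx)], ids=list(ids[idx]))
        sub_m = DistanceMatrix(md[np.ix_(idx, idx)], ids=list(ids[idx]))
        rs[s], ps[s] = mantel(sub_h, sub_m, n_permutations=n_permutations,
                              seed=perm_seeds[s])
    return MantelBatchResult(r_values=rs, p_values=ps, subsample_size=k,
                             n_resamplings=n_resamplings,
                             n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    Deterministic: among tied minimum distances the pair with the
    lexicographically smallest (representative id) pair merges first.  Merge
    height is half the between-cluster average distance, so the tree is
    ultrametric and the first merged pair's cophenetic distance equals their
    input distance.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 ids")
    taxa = dendropy.TaxonNamespace(ids)
    # cluster state: key -> (representative label, member leaf count, node, height)
    nodes: dict[int, dendropy.Node] = {}
    rep: dict[int, str] = {}
    size: dict[int, int] = {}
    height: dict[int, float] = {}
    for i, label in enumerate(ids):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[i], rep[i], size[i], height[i] = node, label, 1, 0.0
    dist: dict[frozenset, float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[frozenset((i, j))] = float(dm.data[i, j])
    active = set(nodes)
    next_key = len(ids)
    while len(active) > 1:
        best = min(
            (pair for pair in dist if pair <= active),
            key=lambda pair: (dist[pair], tuple(sorted(rep[k] for k in pair))),
        )
        i, j = sorted(best, key=lambda k: rep[k])
        d = dist[best]
        h = d / 2.0
        parent = dendropy.Node()
        for child in (i, j):
            nodes[child].edge.length = max(h - height[child], 0.0)
            parent.add_child(nodes[child])
        k = next_key
        next_key += 1
        nodes[k], rep[k], size[k], height[k] = parent, min(rep[i], rep[j]), size[i] + size[j], h
        active -= {i, j}
        for other in active:
            dio = dist.pop(frozenset((i, other)))
            djo = dist.pop(frozenset((j, other)))
            dist[frozenset((k, other))] = (size[i] * dio + size[j] * djo) / size[k]
        del dist[best]
        active.add(k)
    root = nodes[active.pop()]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length distances of a dendrogram."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# tree-distance metrics (rooted, cluster-based)
# ---------------------------------------------------------------------------

def _as_clusters(tree) -> tuple[set[frozenset], frozenset]:
    t = tree.tree if isinstance(tree, HostTree) else tree
    leaves = frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())
    return tree_clusters(t), leaves


def _check_leaves(l1: frozenset, l2: frozenset) -> None:
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )


def rf_distance(t1, t2) -> int:
    """Rooted Robinson-Foulds distance: symmetric difference of the two trees'
    non-trivial cluster sets."""
    c1, l1 = _as_clusters(t1)
    c2, l2 = _as_clusters(t2)
    _check_leaves(l1, l2)
    return len(c1 ^ c2)


def _masks(clusters: list[frozenset], index: dict) -> list[int]:
    return [sum(1 << index[x] for x in c) for c in clusters]


def _mc_from_masks(a: list[int], b: list[int]) -> int:
    """Min-weight perfect matching of bitmask cluster lists (padded with 0)."""
    m = max(len(a), len(b))
    if m == 0:
        return 0
    a = np.array(a + [0] * (m - len(a)), dtype=np.uint64)
    b = np.array(b + [0] * (m - len(b)), dtype=np.uint64)
    cost = np.bitwise_count(a[:, None] ^ b[None, :])
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def _mc_from_clusters(c1: set[frozenset], c2: set[frozenset]) -> int:
    labels = sorted(set().union(*c1, *c2)) if (c1 or c2) else []
    index = {x: i for i, x in enumerate(labels)}
    if len(labels) <= 64:
        return _mc_from_masks(_masks(list(c1), index), _masks(list(c2), index))
    a, b = list(c1), list(c2)
    m = max(len(a), len(b))
    a += [frozenset()] * (m - len(a))
    b += [frozenset()] * (m - len(b))
    cost = np.array([[len(x ^ y) for y in b] for x in a])
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def mc_distance(t1, t2) -> int:
    """Matching Cluster distance: minimum total symmetric-difference weight
    over perfect matchings of the two trees' non-trivial cluster lists
    (padded with empty sets), via the Hungarian assignment algorithm."""
    c1, l1 = _as_clusters(t1)
    c2, l2 = _as_clusters(t2)
    _check_leaves(l1, l2)
    return _mc_from_clusters(c1, c2)


# ---------------------------------------------------------------------------
# congruence test
# ---------------------------------------------------------------------------

@dataclass
class CongruenceResult:
    rf: int
    mc: int
    nrf: float
    nmc: float
    p_rf: float
    p_mc: float
    null_rf: np.ndarray
    null_mc: np.ndarray
    n_leaves: int
    n_permutations: int
    normalization: str = "null_max"


def congruence_test(host, dendro, n_permutations: int = 999,
                    seed: int | None = None,
                    normalization: str = "null_max") -> CongruenceResult:
    """Topological congruence of a microbiota dendrogram with the host tree.

    The null relabels the dendrogram tips by random bijections; small
    distances mean congruence, so p = (1 + #{null <= observed}) / (B + 1).
    nRF divides by 2(n-2), the maximum symmetric difference between two
    rooted trees on n leaves; nMC divides by the null's maximum (default) or
    mean MC.  Both are clipped to [0, 1].
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    if normalization not in ("null_max", "null_mean"):
        raise ValueError(f"unknown normalization {normalization!r}")
    c_host, l_host = _as_clusters(host)
    c_den, l_den = _as_clusters(dendro)
    _check_leaves(l_host, l_den)
    n = len(l_host)
    if n < 4:
        raise ValueError("congruence test degenerate below 4 leaves")
    rf_obs = len(c_host ^ c_den)
    mc_obs = _mc_from_clusters(c_host, c_den)

    labels = sorted(l_den)
    rng = np.random.default_rng(seed)
    null_rf = np.empty(n_permutations, dtype=int)
    null_mc = np.empty(n_permutations, dtype=int)
    if n <= 64:
        index = {x: i for i, x in enumerate(labels)}
        host_masks = _masks(list(c_host), index)
        host_mask_set = set(host_masks)
        den_idx = [tuple(index[x] for x in c) for c in c_den]
        for b in range(n_permutations):
            perm = rng.permutation(n)
            perm_masks = list({sum(1 << int(perm[i]) for i in c) for c in den_idx})
            null_rf[b] = len(host_mask_set ^ set(perm_masks))
            null_mc[b] = _mc_from_masks(host_masks, perm_masks)
    else:
        for b in range(n_permutations):
            perm = rng.permutation(n)
            relabel = {labels[i]: labels[perm[i]] for i in range(n)}
            c_perm = {frozenset(relabel[x] for x in c) for c in c_den}
            null_rf[b] = len(c_host ^ c_perm)
            null_mc[b] = _mc_from_clusters(c_host, c_perm)
    p_rf = (1.0 + np.sum(null_rf <= rf_obs)) / (n_permutations + 1.0)
    p_mc = (1.0 + np.sum(null_mc <= mc_obs)) / (n_permutations + 1.0)
    nrf = rf_obs / (2.0 * (n - 2))
    denom = float(null_mc.max()) if normalization == "null_max" else float(null_mc.mean())
    nmc = 0.0 if mc_obs == 0 else (mc_obs / denom if denom > 0 else 1.0)
    return CongruenceResult(
        rf=rf_obs, mc=mc_obs,
        nrf=float(np.clip(nrf, 0.0, 1.0)), nmc=float(np.clip(nmc, 0.0, 1.0)),
        p_rf=float(p_rf), p_mc=float(p_mc),
        null_rf=null_rf, null_mc=null_mc,
        n_leaves=n, n_permutations=n_permutations, normalization=normalization,
    )
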
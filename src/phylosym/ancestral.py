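"""Brownian-motion ancestral reconstruction and phylogenetic heritability.

Traits (per-taxon relative abundances across host species) evolve under
Brownian motion (BM) on the host tree: tip values are jointly Gaussian with
covariance C, where C[i, j] is the shared root-to-MRCA path length of tips
i and j.  The root state is the generalized least squares (GLS) estimate

    a_hat = (1' C^-1 1)^-1 1' C^-1 y,   sigma2_ML = (y - a_hat 1)' C^-1 (y - a_hat 1) / n

and every internal node's state is the Gaussian conditional expectation
E[x_node | tips] = a_hat + c' C^-1 (y - a_hat 1) with c[i] the shared path
length of the node and tip i — identical to re-rooting the tree at that node
and taking the GLS root estimate.  The root additionally carries an
empirical-Bayes posterior SD (flat root prior, sigma2 fixed at its ML value).

Phylogenetic heritability h2 fits the two-variance model
y ~ N(a 1, sigma2_phylo C + sigma2_e I) by ML over the mixing proportion and
reports the tree-structured share of variance at the average tip depth, in
percent.  On an ultrametric depth-scaled tree this coincides with Pagel's
lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .abundance import AbundanceTable
from .trees import HostTree


# ---------------------------------------------------------------------------
# covariance structure
# ---------------------------------------------------------------------------

def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def bm_covariance(host: HostTree, species: list[str]) -> np.ndarray:
    """BM tip covariance: C[i, j] = depth of MRCA(i, j), C[i, i] = tip depth."""
    mapping = host.find_tips(species)
    tree = host.tree
    depths = _node_depths(tree)
    label_to_idx = {mapping[sp]: i for i, sp in enumerate(species)}
    n = len(species)
    c = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx = label_to_idx.get(node.taxon.label)
            node._ps_leaves = [idx] if idx is not None else []
            if idx is not None:
                c[idx, idx] = depths[node]
            continue
        children = node.child_nodes()
        groups = [ch._ps_leaves for ch in children]
        d = depths[node]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        c[a, b] = c[b, a] = d
        node._ps_leaves = [x for g in groups for x in g]
    return c


def _solve_spd(c: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(c), rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular BM covariance; adding ridge 1e-10")
        return cho_solve(cho_factor(c + 1e-10 * np.eye(c.shape[0])), rhs)


# ---------------------------------------------------------------------------
# GLS root and ancestral states
# ---------------------------------------------------------------------------

def bm_gls_root(y, host: HostTree, species: list[str] | None = None
                ) -> tuple[float, float]:
    """GLS root estimate and ML Brownian rate for one trait.

    ``y`` may be a mapping/Series keyed by species or an array aligned with
    ``species``.
    """
    y, species = _align_trait(y, host, species)
    c = bm_covariance(host, species)
    return _gls_from_cov(y, c)


def _gls_from_cov(y: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    n = len(y)
    ones = np.ones(n)
    ci_1 = _solve_spd(c, ones)
    a_hat = float(ci_1 @ y) / float(ci_1 @ ones)
    resid = y - a_hat
    sigma2 = float(resid @ _solve_spd(c, resid)) / n
    return a_hat, sigma2


def _align_trait(y, host: HostTree, species):
    if species is None:
        if isinstance(y, pd.Series):
            species = list(y.index)
        elif isinstance(y, dict):
            species = sorted(y)
        else:
            raise ValueError("species order required for array traits")
    if isinstance(y, (pd.Series, dict)):
        y = np.array([float(y[sp]) for sp in species])
    else:
        y = np.asarray(y, dtype=float)
    if len(y) != len(species):
        raise ValueError("trait length does not match species list")
    host.find_tips(species)  # raises on unknown species
    return y, list(species)


@dataclass
class NodeEstimates:
    """Per-internal-node BM conditional expectations for one trait."""

    root: float
    root_sd: float
    sigma2: float
    estimates: dict  # internal node label -> estimate (includes "root")


def label_internal_nodes(tree: dendropy.Tree) -> list[str]:
    """Assign stable labels root, N1, N2... (preorder) to unlabeled internals."""
    labels = []
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.parent_node is None:
            node.label = node.label or "root"
        elif not node.label:
            counter += 1
            node.label = f"N{counter}"
        labels.append(node.label)
    return labels


def bm_ancestral_states(y, host: HostTree, species: list[str] | None = None
                        ) -> NodeEstimates:
    """Conditional-expectation ancestral states at every internal node."""
    y, species = _align_trait(y, host, species)
    tree = host.tree
    label_internal_nodes(tree)
    c = bm_covariance(host, species)
    a_hat, sigma2 = _gls_from_cov(y, c)
    ones = np.ones(len(y))
    ci_resid = _solve_spd(c, y - a_hat)
    ci_1 = _solve_spd(c, ones)
    root_sd = float(np.sqrt(max(sigma2 / float(ci_1 @ ones), 0.0)))

    mapping = host.find_tips(species)
    label_to_idx = {mapping[sp]: i for i, sp in enumerate(species)}
    depths = _node_depths(tree)
    estimates = {}
    # shared path of internal node k with tip i = depth of MRCA(k, i):
    # depth(k) for descendants of k, else depth of the MRCA on k's root path.
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        cov = np.zeros(len(y))
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        anc = node
        while anc is not None:
            d = depths[anc]
            for leaf_label in (leaf.taxon.label for leaf in anc.leaf_iter()):
                idx = label_to_idx.get(leaf_label)
                if idx is not None and cov[idx] == 0.0:
                    cov[idx] = depths[node] if leaf_label in below else d
            anc = anc.parent_node
        estimates[node.label] = a_hat + float(cov @ ci_resid)
    return NodeEstimates(root=a_hat, root_sd=root_sd, sigma2=sigma2,
                         estimates=estimates)


# ---------------------------------------------------------------------------
# phylogenetic heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityFit:
    h2_percent: float
    sigma2_phylo: float
    sigma2_e: float
    root: float
    log_likelihood: float
    converged: bool


def phylo_heritability(y, host: HostTree, species: list[str] | None = None
                       ) -> HeritabilityFit:
    """ML fit of y ~ N(a 1, sigma2_phylo C + sigma2_e I); h2 in percent.

    The mixing proportion h parametrizes V = h C/c_bar + (1-h) I with c_bar
    the mean tip depth; h equals the phylogeny-attributable variance share at
    the average tip, so h2 = 100 h.
    """
    y, species = _align_trait(y, host, species)
    n = len(y)
    if n < 8:
        warnings.warn("heritability estimates are unstable below 8 species")
    c = bm_covariance(host, species)
    c_bar = float(np.mean(np.diag(c)))
    if c_bar <= 0:
        raise ValueError("tree has zero total depth")
    evals, evecs = np.linalg.eigh(c / c_bar)
    evals = np.clip(evals, 0.0, None)
    y_t = evecs.T @ y
    one_t = evecs.T @ np.ones(n)

    def profile(h: float):
        d = h * evals + (1.0 - h)
        d = np.maximum(d, 1e-12)
        w = 1.0 / d
        a = float((one_t * w) @ y_t) / float((one_t * w) @ one_t)
        r = y_t - a * one_t
        rss = float((r * r) @ w)
        sigma2 = max(rss / n, 1e-300)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(d)) + n)
        return ll, a, sigma2

    res = minimize_scalar(lambda h: -profile(h)[0], bounds=(0.0, 1.0),
                          method="bounded", options={"xatol": 1e-8})
    h = float(np.clip(res.x, 0.0, 1.0))
    ll, a, sigma2 = profile(h)
    # prefer an exact boundary when it is at least as likely
    for hb in (0.0, 1.0):
        llb, ab, s2b = profile(hb)
        if llb >= ll:
            h, ll, a, sigma2 = hb, llb, ab, s2b
    return HeritabilityFit(
        h2_percent=100.0 * h,
        sigma2_phylo=sigma2 * h / c_bar,
        sigma2_e=sigma2 * (1.0 - h),
        root=a,
        log_likelihood=ll,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# composition-level reconstruction
# ---------------------------------------------------------------------------

def top_taxa(table: AbundanceTable, n: int) -> list[str]:
    """The n most abundant taxa by mean relative abundance (ties lexicographic)."""
    if n > table.n_taxa:
        raise ValueError(f"requested {n} taxa but table has {table.n_taxa}")
    means = table.data.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:n]


def pool_other(table: AbundanceTable, n: int, other_label: str = "Other"
               ) -> AbundanceTable:
    """Keep the top n taxa; pool the rest into one 'Other' column."""
    keep = top_taxa(table, n)
    rest = [t for t in table.taxon_ids if t not in keep]
    df = table.data[keep].copy()
    if rest:
        df[other_label] = table.data[rest].sum(axis=1)
    return AbundanceTable(df, rank=table.rank, is_relative=table.is_relative)


@dataclass
class AncestralStates:
    """Per-node trait estimates and renormalized compositions."""

    taxa: list[str]
    raw: pd.DataFrame           # nodes x taxa, unconstrained BM estimates
    composition: pd.DataFrame   # nodes x taxa, clipped at 0 and renormalized
    root_posterior_sd: pd.Series
    tree: HostTree              # pruned tree with labeled internal nodes


def reconstruct_composition(table: AbundanceTable, host: HostTree,
                            n_taxa: int = 14) -> AncestralStates:
    """Ancestral community composition at every internal node of the host tree.

    Rows of ``table`` are per-species relative-abundance profiles.  The top
    ``n_taxa`` taxa (rest pooled as 'Other') each get an independent BM
    reconstruction; per node the estimates are clipped at zero and rescaled
    to sum to one.  Species missing from the table are pruned from the tree.
    """
    if not table.is_relative:
        raise ValueError("species profiles must be relative abundances")
    species = table.sample_ids
    tree_species = list(species)
    pruned = host.restrict_to(tree_species)
    if pruned.n_tips < host.n_tips:
        warnings.warn(
            f"{host.n_tips - pruned.n_tips} tree tips without profiles pruned"
        )
    pooled = pool_other(table, min(n_taxa, table.n_taxa))
    label_internal_nodes(pruned.tree)
    raw_cols, sd = {}, {}
    for taxon in pooled.taxon_ids:
        fit = bm_ancestral_states(pooled.data[taxon], pruned, species=tree_species)
        raw_cols[taxon] = pd.Series(fit.estimates)
        sd[taxon] = fit.root_sd
    raw = pd.DataFrame(raw_cols)
    clipped = raw.clip(lower=0.0)
    totals = clipped.sum(axis=1)
    if (totals <= 0).any():
        warnings.warn("node with all-zero clipped estimates; using uniform composition")
        clipped.loc[totals <= 0] = 1.0
        totals = clipped.sum(axis=1)
    comp = clipped.div(totals, axis=0)
    return AncestralStates(taxa=list(pooled.taxon_ids), raw=raw, composition=comp,
                           root_posterior_sd=pd.Series(sd), tree=pruned)
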
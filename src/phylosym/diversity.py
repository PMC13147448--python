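"""Alpha/beta diversity, between-site composition correlation, and
significance letter groups.

Shannon entropy is reported in nats by default.  Beta diversity supports
Bray-Curtis (quantitative) and unweighted Jaccard (presence/absence).
Group letters come from a Kruskal-Wallis omnibus followed by Dunn's pairwise
tests with Benjamini-Hochberg correction, rendered as a compact letter
display: groups sharing a letter are not significantly different.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy as _scipy_entropy
from scipy.stats import false_discovery_control, kruskal, norm, rankdata
from skbio import DistanceMatrix

from .abundance import AbundanceTable, SampleMetadata, to_relative


def shannon(row, base: float | None = None) -> float:
    """Shannon entropy of one abundance vector (nats unless ``base`` given)."""
    p = np.asarray(row, dtype=float)
    if p.ndim != 1:
        raise ValueError("shannon expects a 1-D vector")
    if (p < 0).any():
        raise ValueError("negative abundances")
    if p.sum() == 0:
        raise ValueError("all-zero abundance vector")
    return float(_scipy_entropy(p, base=base))


def alpha_diversity(table: AbundanceTable, base: float | None = None) -> pd.Series:
    """Per-sample Shannon entropy."""
    values = [shannon(row, base=base) for row in table.matrix]
    return pd.Series(values, index=table.data.index, name="shannon")


def beta_matrix(table: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise beta diversity between samples.

    ``bray_curtis`` uses the quantitative rows as given; ``jaccard`` is the
    unweighted (binary) form on presence/absence with threshold > 0.
    """
    x = table.matrix
    if metric == "bray_curtis":
        condensed = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        condensed = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def site_correlation(table: AbundanceTable, metadata: SampleMetadata) -> pd.DataFrame:
    """Pearson correlation of mean relative-abundance profiles between body sites."""
    rel = to_relative(table)
    sites = metadata.sites_of(rel.sample_ids).to_numpy()
    profiles = rel.data.groupby(sites).mean()
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 shared taxa")
    if (profiles.std(axis=1) == 0).any():
        warnings.warn("zero-variance site profile; correlations will be NaN")
    return profiles.T.corr(method="pearson")


# ---------------------------------------------------------------------------
# significance letters
# ---------------------------------------------------------------------------

def dunn_posthoc(values, groups) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests with tie correction.

    Returns a symmetric DataFrame of two-sided uncorrected p-values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    n = len(values)
    ranks = rankdata(values)
    # tie correction term: sum(t^3 - t) over tied groups
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    size = {g: int((groups == g).sum()) for g in levels}
    p = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    for i, gi in enumerate(levels):
        for gj in levels[i + 1:]:
            se = np.sqrt(var_base * (1.0 / size[gi] + 1.0 / size[gj]))
            z = 0.0 if se == 0 else (mean_rank[gi] - mean_rank[gj]) / se
            pv = 2.0 * norm.sf(abs(z))
            p.loc[gi, gj] = p.loc[gj, gi] = pv
    return p


def _compact_letters(levels: list, significant: set[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant`` holds unordered level pairs that differ; the result maps
    each level to a letter string such that two levels share a letter iff
    their pair is not significant.
    """
    letters: list[set] = [set(levels)]
    for a, b in sorted(significant, key=lambda p: (str(p[0]), str(p[1]))):
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                letters.extend([s - {a}, s - {b}])
        # absorb letters contained in another
        letters = [s for s in letters
                   if not any(s < t for t in letters if t is not s)]
        # deduplicate
        seen, uniq = set(), []
        for s in letters:
            key = frozenset(s)
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        letters = uniq
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters.sort(key=lambda s: min(levels.index(g) for g in s))
    out = {g: "" for g in levels}
    for ch, s in zip(alphabet, letters):
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


@dataclass
class AlphaResult:
    """Per-sample entropies plus the per-group significance letters."""

    values: pd.Series
    groups: pd.Series
    letters: dict
    kruskal_p: float
    pairwise_p: pd.DataFrame | None


def letter_groups(values, groups, alpha: float = 0.05) -> dict:
    """Compact letter display for group differences in a numeric variable.

    Kruskal-Wallis omnibus at ``alpha``; if significant, Dunn pairwise tests
    with BH correction decide which group pairs differ.  Groups with fewer
    than two observations are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in pd.unique(groups)]
    small = [g for g in levels if (groups == g).sum() < 2]
    if small:
        warnings.warn(f"dropping groups with <2 observations: {small}")
        keep = ~np.isin(groups, small)
        values, groups = values[keep], groups[keep]
        levels = [g for g in levels if g not in small]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with >=2 observations")
    samples = [values[groups == g] for g in levels]
    try:
        _, kw_p = kruskal(*samples)
    except ValueError:  # all values identical
        kw_p = 1.0
    # order levels by median so letter 'a' goes to the lowest group
    levels = sorted(levels, key=lambda g: np.median(values[groups == g]))
    if kw_p >= alpha:
        return {g: "a" for g in levels}
    praw = dunn_posthoc(values, groups)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    padj = false_discovery_control([praw.loc[a, b] for a, b in pairs], method="bh")
    significant = {pair for pair, p in zip(pairs, padj) if p < alpha}
    return _compact_letters(levels, significant)


def alpha_with_letters(table: AbundanceTable, metadata: SampleMetadata,
                       alpha: float = 0.05, base: float | None = None) -> AlphaResult:
    """Shannon entropy per sample with body-site letter groups."""
    values = alpha_diversity(table, base=base)
    groups = metadata.sites_of(table.sample_ids)
    samples = [values[groups == g].to_numpy() for g in pd.unique(groups)
               if (groups == g).sum() >= 2]
    kw_p = kruskal(*samples)[1] if len(samples) >= 2 else np.nan
    letters = letter_groups(values.to_numpy(), groups.to_numpy(), alpha=alpha)
    praw = dunn_posthoc(values.to_numpy(), groups.to_numpy()) if len(samples) >= 2 else None
    return AlphaResult(values=values, groups=groups, letters=letters,
                       kruskal_p=float(kw_p), pairwise_p=praw)
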
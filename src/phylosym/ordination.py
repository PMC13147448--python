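"""Principal coordinates analysis and distance-based PERMANOVA.

PERMANOVA follows the Gower-centered inner-product decomposition with
sequential (Type-I) sums of squares, free permutation of observations, and a
partial omega-squared effect size per term:

    omega2_p = (SS_term - df_term * MS_res) / (SS_term + (N - df_term) * MS_res)

the distance-based analogue of the classical ANOVA adjustment, so effect
sizes are comparable across terms and designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth
from skbio import DistanceMatrix


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # per returned axis, on positive-eigenvalue sum
    n_negative_eigenvalues: int


def pcoa(dm: DistanceMatrix, axes: int = 2) -> PcoaResult:
    """Classical PCoA by eigendecomposition of the Gower-centered matrix.

    Negative eigenvalues (non-Euclidean distances) are counted and reported,
    not corrected.  Requested axes are truncated to the number of positive
    eigenvalues, with a warning.
    """
    if axes < 2:
        raise ValueError("axes must be >= 2")
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d**2
    g = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals[0]), 1.0)
    positive = vals > tol
    n_pos = int(positive.sum())
    n_neg = int((vals < -tol).sum())
    if axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating axes from {axes}")
        axes = n_pos
    coords = vecs[:, :axes] * np.sqrt(vals[:axes])
    prop = vals[:axes] / vals[positive].sum()
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{i+1}" for i in range(axes)])
    return PcoaResult(coordinates=frame, eigenvalues=vals,
                      proportion_explained=prop, n_negative_eigenvalues=n_neg)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTerm:
    name: str
    ss: float
    df: int
    pseudo_f: float
    p_value: float
    omega_squared_partial: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int
    term_order: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(term=t.name, SS=t.ss, df=t.df, pseudo_F=t.pseudo_f,
                 p_value=t.p_value, omega2_partial=t.omega_squared_partial)
            for t in self.terms
        ]
        rows.append(dict(term="Residual", SS=self.residual_ss,
                         df=self.residual_df, pseudo_F=np.nan, p_value=np.nan,
                         omega2_partial=np.nan))
        return pd.DataFrame(rows).set_index("term")


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """One-hot design columns for a factor or a ':'-separated interaction."""
    factors = term.split(":")
    combo = metadata[factors[0]].astype(str)
    for f in factors[1:]:
        combo = combo + "\x1f" + metadata[f].astype(str)
    return pd.get_dummies(combo).to_numpy(dtype=float)


def _gower(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame, terms: list[str],
              n_permutations: int = 999, seed: int | None = None) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA with partial omega-squared effect sizes.

    ``terms`` are factor names from ``metadata`` (indexed by sample id);
    interactions are written ``a:b``.  Pseudo-F per term uses the residual
    mean square of the full model; p-values come from ``n_permutations`` free
    permutations of observations with the +1 correction.  Factors with a
    single level are dropped with a warning; a term adding no rank to the
    design (confounded) is an error.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    meta = metadata.loc[list(dm.ids)]
    kept_terms = []
    for t in terms:
        levels_ok = all(meta[f].nunique() > 1 for f in t.split(":"))
        if not levels_ok:
            warnings.warn(f"term {t!r} has a single level; dropped")
        else:
            kept_terms.append(t)
    if not kept_terms:
        raise ValueError("no usable terms")
    n = len(dm.ids)
    g = _gower(dm.data)
    total_ss = float(np.trace(g))

    # cumulative hat matrices (intercept included implicitly: G is centered)
    hats, dfs = [], []
    x = np.ones((n, 1))
    prev_rank = 1
    for t in kept_terms:
        x = np.hstack([x, _design_columns(meta, t)])
        basis = orth(x)
        rank = basis.shape[1]
        df_t = rank - prev_rank
        if df_t <= 0:
            raise ValueError(f"term {t!r} is confounded with earlier terms")
        hats.append(basis @ basis.T)
        dfs.append(df_t)
        prev_rank = rank

    def seq_stats(gm: np.ndarray):
        """Sequential SS per term and residual SS for a (permuted) Gower matrix."""
        cum = [float(np.sum(gm * h)) for h in hats]  # tr(G H_k)
        ss = np.diff([0.0] + cum)
        ss_res = float(np.trace(gm)) - cum[-1]
        return ss, ss_res

    ss_terms, ss_res = seq_stats(g)
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ms_res = ss_res / df_res
    f_obs = np.array([(ss_terms[k] / dfs[k]) / ms_res for k in range(len(kept_terms))])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept_terms))
    for _ in range(n_permutations):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_p, ss_res_p = seq_stats(gp)
        ms_res_p = ss_res_p / df_res
        f_p = np.array([(ss_p[k] / dfs[k]) / ms_res_p for k in range(len(kept_terms))])
        exceed += f_p >= f_obs
    p_values = (1.0 + exceed) / (n_permutations + 1.0)

    out = []
    for k, t in enumerate(kept_terms):
        omega = (ss_terms[k] - dfs[k] * ms_res) / (ss_terms[k] + (n - dfs[k]) * ms_res)
        out.append(PermanovaTerm(name=t, ss=float(ss_terms[k]), df=dfs[k],
                                 pseudo_f=float(f_obs[k]), p_value=float(p_values[k]),
                                 omega_squared_partial=float(omega)))
    return PermanovaResult(terms=out, residual_ss=float(ss_res), residual_df=df_res,
                           total_ss=total_ss, n_permutations=n_permutations,
                           term_order=kept_terms)
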
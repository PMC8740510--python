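"""Community structure: Bray-Curtis, PCoA, PERMANOVA, ANOSIM, UPGMA.

PERMANOVA is the distance-based linear model of McArdle & Anderson:
the Gower-centered matrix G is partitioned by sequential (Type I) hat-matrix
projections of the design, pseudo-F uses the residual mean square, and
p-values come from free permutation of sample labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables import DistanceMatrix, OtuTable, SampleFrame, TreeNode

__all__ = [
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "PermanovaTable",
    "permanova",
    "AnosimResult",
    "anosim",
    "hierarchical_cluster",
]


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on counts."""
    if table.n_samples < 2:
        raise ValueError("bray_curtis needs at least 2 samples")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass
class OrdinationResult:
    sample_ids: list
    coordinates: np.ndarray          # samples x axes, positive eigenvalues only
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates: eigendecomposition of -0.5 J D^2 J.

    Coordinates are eigenvector * sqrt(eigenvalue) for positive eigenvalues;
    negative eigenvalues are reported in ``eigenvalues`` but contribute no
    axes and are excluded from the explained-proportion denominator.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n = dm.n
    d2 = dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2.0
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10 * abs(evals[0]), 1e-12) if n else evals > 0
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            f"truncating", stacklevel=2)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pos_sum = evals[pos].sum() if n_pos else 1.0
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=evals[:k] / pos_sum,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower(dm_values: np.ndarray) -> np.ndarray:
    n = dm_values.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dm_values**2) @ j
    return (g + g.T) / 2.0


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Treatment-free one-hot encoding of a main effect or 'A x B' interaction."""
    parts = [p.strip() for p in term.replace("×", "x").split(" x ")]
    for p in parts:
        if p not in design.columns:
            raise ValueError(f"term {term!r}: column {p!r} not in design")
        if design[p].nunique() < 2:
            raise ValueError(f"term {term!r}: factor {p!r} has < 2 levels")
    combo = design[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + ":" + design[p].astype(str)
    return pd.get_dummies(combo, dtype=float).to_numpy()


def _projector(x: np.ndarray) -> tuple:
    """Orthogonal projector onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


@dataclass
class PermanovaTable:
    terms: list            # term names, in fitting order
    df: dict               # name -> degrees of freedom (incl. Residual, Total)
    ss: dict               # name -> sum of squares
    pseudo_f: dict         # name -> pseudo-F (terms only)
    r2: dict               # name -> R^2 (terms + Residual)
    p: dict                # name -> permutation p (terms only)
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms + ["Residual", "Total"]:
            rows.append({
                "term": t,
                "df": self.df[t],
                "SS": self.ss[t],
                "F": self.pseudo_f.get(t, np.nan),
                "R2": self.r2.get(t, np.nan),
                "P": self.p.get(t, np.nan),
            })
        return pd.DataFrame(rows).set_index("term")


def _permanova_f(g, projectors, dfs, n, rank_full):
    """Sequential SS and pseudo-F for each term given the Gower matrix."""
    ss_total = np.trace(g)
    prev = np.ones((n, n)) / n  # intercept projector
    ss_terms = []
    for proj in projectors:
        ss_terms.append(float(np.sum((proj - prev) * g)))
        prev = proj
    ss_resid = float(np.sum((np.eye(n) - prev) * g))
    df_resid = n - 1 - sum(dfs)
    fs = [
        (ss_t / df_t) / (ss_resid / df_resid) if df_resid > 0 else np.nan
        for ss_t, df_t in zip(ss_terms, dfs)
    ]
    return np.array(ss_terms), ss_resid, float(ss_total), np.array(fs), df_resid


def permanova(dm: DistanceMatrix, design: SampleFrame, terms,
              n_perm: int = 999, seed=None, strata=None) -> PermanovaTable:
    """Sequential (Type I) PERMANOVA over main effects and 'A x B' interactions.

    p-values use the (1 + #{F_perm >= F_obs}) / (1 + n_perm) estimator under
    free permutation of sample labels (or permutation within the levels of
    a ``strata`` design column, when given).  Deterministic given ``seed``.
    """
    df_design = design.aligned_to(dm.sample_ids) if isinstance(design, SampleFrame) \
        else design.loc[list(dm.sample_ids)]
    n = dm.n
    g = _gower(dm.d)

    cum = np.ones((n, 1))
    projectors, dfs = [], []
    rank_prev = 1
    for term in terms:
        cum = np.hstack([cum, _term_columns(df_design, term)])
        proj, rank = _projector(cum)
        df_t = rank - rank_prev
        if df_t == 0:
            raise ValueError(
                f"term {term!r} is confounded with earlier terms (adds no rank)")
        projectors.append(proj)
        dfs.append(df_t)
        rank_prev = rank

    ss_terms, ss_resid, ss_total, f_obs, df_resid = _permanova_f(
        g, projectors, dfs, n, rank_prev)
    if df_resid <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")

    rng = np.random.default_rng(seed)
    if strata is not None:
        if strata not in df_design.columns:
            raise ValueError(f"strata column {strata!r} not in design")
        strata_groups = [np.where(df_design[strata].to_numpy() == lev)[0]
                         for lev in pd.unique(df_design[strata])]

    def draw_perm():
        if strata is None:
            return rng.permutation(n)
        perm = np.arange(n)
        for idx in strata_groups:
            perm[idx] = idx[rng.permutation(len(idx))]
        return perm

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = draw_perm()
        gp = g[np.ix_(perm, perm)]
        _, _, _, f_perm, _ = _permanova_f(gp, projectors, dfs, n, rank_prev)
        exceed += f_perm >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    names = list(terms)
    table = PermanovaTable(
        terms=names,
        df={**dict(zip(names, dfs)), "Residual": df_resid, "Total": n - 1},
        ss={**dict(zip(names, ss_terms)), "Residual": ss_resid, "Total": ss_total},
        pseudo_f=dict(zip(names, f_obs)),
        r2={**{t: s / ss_total for t, s in zip(names, ss_terms)},
            "Residual": ss_resid / ss_total},
        p=dict(zip(names, pvals)),
        n_permutations=n_perm,
    )
    return table


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray) -> float:
    n = within_mask.shape[0]
    m = n * (n - 1) / 2.0
    iu = np.triu_indices(n, k=1)
    within = within_mask[iu]
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None) -> AnosimResult:
    """Clarke's ANOSIM R with mid-ranks and a free-permutation p-value."""
    groups = np.asarray(groups)
    if groups.shape[0] != dm.n:
        raise ValueError("groups length must match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("anosim needs at least 2 groups")
    if (counts < 2).any():
        bad = labels[counts < 2][0]
        raise ValueError(f"group {bad!r} has fewer than 2 members")
    n = dm.n
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.d[iu])
    same = groups[:, None] == groups[None, :]
    r_obs = _anosim_r(ranks, same)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        gp = groups[rng.permutation(n)]
        same_p = gp[:, None] == gp[None, :]
        if _anosim_r(ranks, same_p) >= r_obs - 1e-12:
            count += 1
    return AnosimResult(r=r_obs, p=(1.0 + count) / (1.0 + n_perm),
                        n_permutations=n_perm)


# ---------------------------------------------------------------------------
# UPGMA


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "average") -> TreeNode:
    """UPGMA merge tree; ties broken by the lowest-index pair.

    Heights are cophenetic distances; leaves sit at height 0.  The newick
    convention (branch length = parent height - child height) then halves
    merge distances on the two sides, as usual for UPGMA.
    """
    if linkage != "average":
        raise ValueError("only average (UPGMA) linkage is supported")
    n = dm.n
    if n < 2:
        if n == 1:
            return TreeNode(height=0.0, label=dm.sample_ids[0])
        raise ValueError("need at least 1 item")
    d = dm.d.astype(float).copy()
    active = list(range(n))
    nodes = {i: TreeNode(height=0.0, label=dm.sample_ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = dist[frozenset((i, j))]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        new = TreeNode(height=dij / 2.0, children=(nodes[i], nodes[j]))
        nodes[next_id] = new
        sizes[next_id] = sizes[i] + sizes[j]
        active.remove(i)
        active.remove(j)
        for k in active:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        dist.pop(frozenset((i, j)))
        active.append(next_id)
        next_id += 1
    return nodes[active[0]]
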
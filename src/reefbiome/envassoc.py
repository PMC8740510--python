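"""OTU-environment association: abundant-OTU selection, Spearman grids,
environmental distances, and Mantel / partial Mantel tests.

Missing environmental values are masked and every pairwise computation
drops masked samples pairwise-complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables import DistanceMatrix, EnvMatrix, OtuTable

__all__ = [
    "abundant_otus",
    "CorrelationGrid",
    "spearman_grid",
    "env_distance",
    "MantelResult",
    "mantel",
    "partial_mantel",
]

STAR_LEVELS = (0.05, 0.01, 0.001)


def abundant_otus(table: OtuTable, min_mean_rel_abund: float = 0.005) -> OtuTable:
    """OTUs whose mean relative abundance exceeds the threshold (strict >),
    ordered by descending mean abundance."""
    mean_ra = table.mean_relative_abundance()
    keep = np.where(mean_ra > min_mean_rel_abund)[0]
    if keep.size == 0:
        warnings.warn("no OTU passes the abundance threshold; empty subset",
                      stacklevel=2)
    order = keep[np.argsort(-mean_ra[keep], kind="stable")]
    return table.select_otus([table.otu_ids[i] for i in order])


def _spearman_pair(x: np.ndarray, y: np.ndarray):
    """Spearman rho via mid-rank Pearson, p from the t approximation."""
    n = x.size
    if n < 4:
        return np.nan, np.nan
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy),
                        -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class CorrelationGrid:
    otu_ids: list
    factor_names: list
    rho: np.ndarray
    p: np.ndarray

    def stars(self) -> np.ndarray:
        """'', '*', '**', '***' per cell at alpha 0.05 / 0.01 / 0.001."""
        out = np.full(self.p.shape, "", dtype=object)
        with np.errstate(invalid="ignore"):
            for stars, alpha in zip(("*", "**", "***"), STAR_LEVELS):
                out[np.where(self.p < alpha)] = stars
        return out

    def to_frames(self):
        rho = pd.DataFrame(self.rho, index=self.otu_ids, columns=self.factor_names)
        p = pd.DataFrame(self.p, index=self.otu_ids, columns=self.factor_names)
        return rho, p


def spearman_grid(table: OtuTable, env: EnvMatrix,
                  bh_correct: bool = False) -> CorrelationGrid:
    """Spearman rho and p for every OTU x environmental factor pair.

    Uses relative abundances; samples are matched by id and masked env
    entries are dropped pairwise-complete.  Constant vectors in a pair give
    a missing (NaN) cell.  BH correction across the grid is off by default.
    """
    shared = [s for s in table.sample_ids if s in set(env.sample_ids)]
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples between table and env")
    t_idx = [table.sample_ids.index(s) for s in shared]
    e_idx = [env.sample_ids.index(s) for s in shared]
    x = table.relative_abundance()[t_idx, :]
    e_vals = env.values[e_idx, :]
    e_mask = env.mask[e_idx, :]

    n_otu, n_fac = table.n_otus, len(env.factor_names)
    rho = np.full((n_otu, n_fac), np.nan)
    p = np.full((n_otu, n_fac), np.nan)
    for f in range(n_fac):
        ok = ~e_mask[:, f]
        if ok.sum() < 4:
            continue
        ev = e_vals[ok, f]
        for o in range(n_otu):
            rho[o, f], p[o, f] = _spearman_pair(x[ok, o], ev)
    if bh_correct:
        flat = p.ravel()
        valid = ~np.isnan(flat)
        if valid.any():
            from statsmodels.stats.multitest import multipletests
            adj = flat.copy()
            adj[valid] = multipletests(flat[valid], method="fdr_bh")[1]
            p = adj.reshape(p.shape)
    return CorrelationGrid(list(table.otu_ids), list(env.factor_names), rho, p)


def env_distance(env: EnvMatrix, factors=None) -> DistanceMatrix:
    """Euclidean distance over z-scored factors (unit-invariant).

    Masked entries are imputed with the factor mean after z-scoring (i.e.
    contribute zero), keeping the matrix well-defined under scattered
    missing values.
    """
    if factors is None:
        factors = list(env.factor_names)
    idx = [env.factor_names.index(f) for f in factors]
    vals = env.values[:, idx].astype(float).copy()
    mask = env.mask[:, idx]
    vals[mask] = np.nan
    mu = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=0)
    for k, f in enumerate(factors):
        if not np.isfinite(sd[k]) or sd[k] == 0:
            raise ValueError(f"factor {f!r} is constant; cannot standardize")
    z = (vals - mu) / sd
    z[np.isnan(z)] = 0.0
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(list(env.sample_ids), d)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    controlled: str = None


def _triangle(dm: DistanceMatrix) -> np.ndarray:
    return dm.condensed()


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method!r}")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.clip(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb),
                         -1.0, 1.0))


def _check_aligned(*dms):
    ids = dms[0].sample_ids
    for dm in dms[1:]:
        if dm.sample_ids != ids:
            raise ValueError("distance matrices must share samples in the same order")


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman",
           n_perm: int = 999, seed=None) -> MantelResult:
    """Mantel correlation of triangle entries; p by jointly permuting the
    rows and columns of ``d1``.  Deterministic given ``seed``."""
    _check_aligned(d1, d2)
    t2 = _triangle(d2)
    r_obs = _corr(_triangle(d1), t2, method)
    rng = np.random.default_rng(seed)
    n = d1.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = d1.d[np.ix_(perm, perm)]
        iu = np.triu_indices(n, k=1)
        if _corr(dp[iu], t2, method) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(1.0 + count) / (1.0 + n_perm),
                        n_permutations=n_perm, method=method)


def partial_mantel(d1: DistanceMatrix, d2: DistanceMatrix, d3: DistanceMatrix,
                   method: str = "spearman", n_perm: int = 999,
                   seed=None) -> MantelResult:
    """First-order partial Mantel r12.3, controlling the third matrix.

    p-value permutes the rows+columns of ``d1`` while holding d2, d3 fixed.
    """
    _check_aligned(d1, d2, d3)
    t2, t3 = _triangle(d2), _triangle(d3)

    def partial_r(t1):
        r12 = _corr(t1, t2, method)
        r13 = _corr(t1, t3, method)
        r23 = _corr(t2, t3, method)
        denom = (1.0 - r13**2) * (1.0 - r23**2)
        if denom <= 1e-12:
            raise ValueError(
                "partial Mantel undefined: a controlling correlation is +-1")
        return (r12 - r13 * r23) / np.sqrt(denom)

    r_obs = partial_r(_triangle(d1))
    rng = np.random.default_rng(seed)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_r(d1.d[np.ix_(perm, perm)][iu]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=float(r_obs), p=(1.0 + count) / (1.0 + n_perm),
                        n_permutations=n_perm, method=method,
                        controlled="d3")
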
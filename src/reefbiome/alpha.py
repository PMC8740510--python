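"""Per-sample alpha diversity estimators and nonparametric group tests.

Estimators operate on raw counts (no rarefaction is applied anywhere in
this package; see docs/methods.md).  Shannon entropy defaults to natural
log; Simpson is reported as the dominance form D = sum(p_i^2) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable

__all__ = [
    "shannon",
    "simpson",
    "chao1",
    "ace",
    "goods_coverage",
    "AlphaRecord",
    "alpha_table",
    "kruskal_wallis",
    "group_letters",
]


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector: diversity undefined")
    return c.astype(float)


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy H = -sum p_i log p_i over positive counts."""
    c = _clean(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def simpson(counts, unbiased: bool = False, inverse_complement: bool = False) -> float:
    """Simpson dominance D = sum p_i^2 (default) or the unbiased estimator.

    With ``inverse_complement=True`` returns 1 - D (Gini-Simpson).
    """
    c = _clean(counts)
    n = c.sum()
    if unbiased:
        if n < 2:
            raise ValueError("unbiased Simpson needs at least 2 reads")
        d = float((c * (c - 1)).sum() / (n * (n - 1)))
    else:
        p = c / n
        d = float((p**2).sum())
    return 1.0 - d if inverse_complement else d


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), bias-corrected when F2 = 0."""
    c = _clean(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (classic ACE).

    Falls back to chao1 when the rare-class coverage C is zero (all rare
    OTUs are singletons).
    """
    c = _clean(counts)
    rare = c[c <= rare_cutoff]
    abund = c[c > rare_cutoff]
    s_abund = abund.size
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        return chao1(counts)
    freq_sum = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max(
            0.0,
            (s_rare / coverage) * freq_sum / (n_rare * (n_rare - 1.0)) - 1.0,
        )
    return float(s_abund + s_rare / coverage + (f1 / coverage) * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: chance the next read is an already-seen OTU."""
    c = _clean(counts)
    return float(1.0 - (c == 1).sum() / c.sum())


@dataclass
class AlphaRecord:
    sample_id: str
    observed_otus: int
    shannon: float
    simpson: float
    chao1: float
    ace: float
    coverage: float


def alpha_table(table: OtuTable, log_base: float = math.e,
                simpson_unbiased: bool = False) -> pd.DataFrame:
    """One alpha-diversity record per sample, as a DataFrame indexed by sample."""
    records = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i, :]
        try:
            rec = AlphaRecord(
                sample_id=sid,
                observed_otus=int((row > 0).sum()),
                shannon=shannon(row, base=log_base),
                simpson=simpson(row, unbiased=simpson_unbiased),
                chao1=chao1(row),
                ace=ace(row),
                coverage=goods_coverage(row),
            )
        except ValueError as e:
            raise ValueError(f"sample {sid!r}: {e}") from e
        records.append(asdict(rec))
    return pd.DataFrame(records).set_index("sample_id")


def kruskal_wallis(values, groups):
    """Kruskal-Wallis H (tie-corrected) and chi-square p over k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def group_letters(values, groups, alpha: float = 0.05) -> dict:
    """Compact letter display from all pairwise Kruskal-Wallis tests.

    Groups share a letter iff they are not significantly different.  Letter
    classes are the maximal cliques of the not-significantly-different
    graph, lettered in order of descending group mean.
    """
    import networkx as nx

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("group_letters needs at least 2 groups")
    means = {g: values[groups == g].mean() for g in labels}

    nonsig_pairs = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            sub = np.isin(groups, [a, b])
            _, p = kruskal_wallis(values[sub], groups[sub])
            if p >= alpha:
                nonsig_pairs.append((a, b))
    return letters_from_pairs(labels, means, nonsig_pairs)


def letters_from_pairs(labels, means, nonsig_pairs) -> dict:
    """Compact letter display given the not-significantly-different pairs.

    Letter classes are the maximal cliques of the non-significance graph,
    lettered in order of the best (highest-mean) member.
    """
    import networkx as nx

    nonsig = nx.Graph()
    nonsig.add_nodes_from(labels)
    nonsig.add_edges_from(nonsig_pairs)
    cliques = [frozenset(c) for c in nx.find_cliques(nonsig)]
    cliques.sort(key=lambda c: (-max(means[g] for g in c),
                                sorted(str(g) for g in c)))
    letters = {g: "" for g in labels}
    for k, clique in enumerate(cliques):
        ch = _letter(k)
        for g in clique:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in labels}


def _letter(k: int) -> str:
    out = ""
    k += 1
    while k:
        k, r = divmod(k - 1, 26)
        out = chr(ord("a") + r) + out
    return out
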
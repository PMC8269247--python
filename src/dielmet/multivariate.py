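"""Sample-level multivariate structure: standardized distances and ANOSIM."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .rhythm import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["DissimilarityMatrix", "standardize_and_distance", "anosim", "pairwise_anosim"]

METRICS = ("euclidean_zscore", "bray_curtis")


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarities with a metric label."""

    data: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if np.any(d < 0):
            raise ValueError("dissimilarities must be nonnegative")
        self.data = d

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


def standardize_and_distance(
    concentrations: pd.DataFrame,
    metric: str = "euclidean_zscore",
) -> DissimilarityMatrix:
    """Pairwise sample dissimilarities from a compound x sample matrix.

    For ``euclidean_zscore`` each compound is z-scored across samples
    before Euclidean distance; ``bray_curtis`` operates on the raw
    (nonnegative) concentrations.  Missing values are imputed as the
    compound's minimum over samples; zero-variance compounds are dropped
    with a warning.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    mat = concentrations.astype(float).copy()
    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(f"all-missing compounds: {list(mat.index[all_missing])}")
    # minimal-assumption imputation: per-compound minimum
    mat = mat.apply(lambda row: row.fillna(row.min()), axis=1)
    variances = mat.var(axis=1)
    dropped = list(mat.index[variances == 0])
    if dropped:
        logger.warning("standardize_and_distance: dropping zero-variance compounds %s", dropped)
        mat = mat.drop(index=dropped)
    x = mat.to_numpy().T  # samples x compounds
    if metric == "euclidean_zscore":
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        d = squareform(pdist(x, metric="euclidean"))
    else:
        d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(d, [str(c) for c in concentrations.columns], metric)


def _anosim_r(ranks_sq: np.ndarray, groups: np.ndarray) -> float:
    n = len(groups)
    within = groups[:, None] == groups[None, :]
    iu = np.triu_indices(n, k=1)
    rw = ranks_sq[iu][within[iu]]
    rb = ranks_sq[iu][~within[iu]]
    m = n * (n - 1) / 2
    return float((rb.mean() - rw.mean()) / (m / 2.0))


def anosim(
    d: DissimilarityMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2), ranks
    taken over all off-diagonal dissimilarities (midranks for ties,
    M = n(n-1)/2).  The p-value is permutational:
    (1 + #{permuted R >= observed}) / (1 + n_permutations), or the exact
    fraction over all distinct relabelings when ``exhaustive``.
    """
    g = np.asarray([str(x) for x in np.asarray(groups)])
    if len(g) != len(d.ids):
        raise ValueError("groups must align with samples")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    n = len(g)
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros_like(d.data)
    ranks[iu] = rankdata(d.data[iu])
    ranks = ranks + ranks.T
    observed = _anosim_r(ranks, g)

    if exhaustive:
        seen = set()
        ge = total = 0
        for perm in itertools.permutations(range(n)):
            key = tuple(g[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if _anosim_r(ranks, np.asarray(key)) >= observed - 1e-12:
                ge += 1
        return observed, ge / total

    if n_permutations < 99:
        raise ValueError("need >= 99 permutations")
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        if _anosim_r(ranks, rng.permutation(g)) >= observed - 1e-12:
            ge += 1
    return observed, (1 + ge) / (1 + n_permutations)


def pairwise_anosim(
    d: DissimilarityMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """ANOSIM between every pair of groups, BH-corrected."""
    g = np.asarray([str(x) for x in np.asarray(groups)])
    labels = sorted(set(g))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(labels, 2):
        sel = np.isin(g, [a, b])
        idx = np.nonzero(sel)[0]
        sub = DissimilarityMatrix(
            d.data[np.ix_(idx, idx)], [d.ids[i] for i in idx], d.metric
        )
        r, p = anosim(sub, g[sel], n_permutations, seed=int(rng.integers(2**31)))
        rows.append({"group_a": a, "group_b": b, "R": r, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out["p"])
    return out
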
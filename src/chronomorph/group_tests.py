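"""Permutational MANOVA (NPMANOVA) on Euclidean distances, one-way and
pairwise, with sequential-Bonferroni (Holm) correction.

Group separation in morphospace is tested non-parametrically: the pseudo-F
statistic is built from sums of squared inter-point distances and its null
distribution obtained by permuting group labels.  Distances are computed on
exactly the axes supplied by the caller (e.g. the leading principal
components); no internal re-ordination happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = ["NpmanovaResult", "npmanova", "pairwise_npmanova", "holm_adjust"]


@dataclass
class NpmanovaResult:
    """One-way NPMANOVA result.

    ``p`` uses the +1 convention — the observed statistic counts as one
    permutation — so the smallest attainable value is 1/(permutations+1).
    """

    f: float
    ss_total: float
    ss_within: float
    ss_among: float
    df_among: int
    df_within: int
    p: float
    permutations: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        assert self.ss_total >= 0 and 0 < self.p <= 1

    def summary(self) -> str:
        return (
            f"NPMANOVA: F = {self.f:.4g} "
            f"(df {self.df_among}, {self.df_within}); "
            f"p = {self.p:.4g} ({self.permutations} permutations)"
        )


def _group_masks(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _ss_within(d2: np.ndarray, masks: Sequence[np.ndarray]) -> float:
    # SS within group g = sum_{i<j in g} d^2_ij / n_g
    return sum(d2[np.ix_(m, m)].sum() / (2 * len(m)) for m in masks)


def npmanova(
    points,
    groups: Sequence[str],
    permutations: int = 9999,
    seed: Optional[int] = None,
    distances: Optional[np.ndarray] = None,
) -> NpmanovaResult:
    """One-way permutational MANOVA on Euclidean distances.

    SS_total = sum of squared pairwise distances / n; SS_within pools the
    same quantity per group; pseudo-F = (SS_among/(a-1)) / (SS_within/(n-a)).
    Significance from ``permutations`` random relabelings.
    """
    labels = np.asarray(groups)
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = list(uniq[counts < 2])
        raise ValueError(f"group(s) of size 1 are not testable: {small}")
    if permutations < 1:
        raise ValueError("need at least one permutation")

    if distances is None:
        X = np.asarray(points, dtype=float)
        if len(X) != n:
            raise ValueError("points/groups length mismatch")
        d2 = squareform(pdist(X, metric="sqeuclidean"))
    else:
        d2 = np.asarray(distances, dtype=float) ** 2

    a = len(uniq)
    ss_total = d2.sum() / (2 * n)
    masks = _group_masks(labels)
    ss_within = _ss_within(d2, masks)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    f_obs = (ss_among / df_among) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    exceed = 0
    sizes = [len(m) for m in masks]
    for _ in range(permutations):
        perm = rng.permutation(n)
        start = 0
        ssw = 0.0
        for sz in sizes:
            m = perm[start:start + sz]
            ssw += d2[np.ix_(m, m)].sum() / (2 * sz)
            start += sz
        f_perm = ((ss_total - ssw) / df_among) / (ssw / df_within)
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return NpmanovaResult(
        f=float(f_obs), ss_total=float(ss_total), ss_within=float(ss_within),
        ss_among=float(ss_among), df_among=df_among, df_within=df_within,
        p=float(p), permutations=permutations, seed=seed,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Sequential-Bonferroni (Holm) adjustment: sort raw p ascending, multiply
    the i-th smallest by (m-i+1), enforce monotonicity, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def pairwise_npmanova(
    points,
    groups: Sequence[str],
    permutations: int = 9999,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """All pairwise NPMANOVA comparisons with Holm-adjusted p values.

    Each pair is tested with its own permutation stream (seeded reproducibly
    from ``seed``).  Returns a long-format frame with columns ``group1``,
    ``group2``, ``f``, ``p_raw``, ``p_adjusted``.
    """
    labels = np.asarray(groups)
    X = np.asarray(points, dtype=float)
    uniq = np.unique(labels)
    pairs = list(combinations(uniq, 2))
    child_seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (g1, g2), ss in zip(pairs, child_seeds):
        mask = np.isin(labels, [g1, g2])
        res = npmanova(
            X[mask], labels[mask], permutations=permutations,
            seed=ss.generate_state(1)[0],
        )
        rows.append(dict(group1=g1, group2=g2, f=res.f, p_raw=res.p))
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_adjust(out["p_raw"].to_numpy())
    return out
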
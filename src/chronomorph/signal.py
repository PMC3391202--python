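"""Phylogenetic signal in trait spaces: phylogenetic eigenvectors (PCO),
independent contrasts, Blomberg's K with permutation significance, and
(multivariate) phylogenetic eigenvector regression.

Two complementary routes quantify how much of the trait variation among
species is structured by the phylogeny: regression of traits on the leading
principal-coordinate axes of the patristic distance matrix (PVR/MPVR), and
Blomberg's K, which compares observed trait variance to its Brownian-motion
expectation on the same tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .tree import TimeTree, TreeError

__all__ = [
    "PcoAxes", "KResult", "PvrResult",
    "pco_eigenvectors", "pic", "blomberg_k", "pvr", "mpvr",
]


# ---------------------------------------------------------------------------
# principal coordinates of the tree
# ---------------------------------------------------------------------------

@dataclass
class PcoAxes:
    """Retained principal-coordinate axes of a tree's distance matrix."""

    scores: pd.DataFrame          # taxa x retained axes
    eigenvalues: np.ndarray       # all positive eigenvalues, descending
    variance_fractions: np.ndarray
    cutoff: float

    @property
    def taxa(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_retained(self) -> int:
        return self.scores.shape[1]


def pco_eigenvectors(
    tree: TimeTree, cutoff: float = 0.95, metric: str = "patristic"
) -> PcoAxes:
    """Principal coordinates analysis of the tree's tip-to-tip distances.

    Pairwise patristic (path-sum) distances are double-centered (Gower) and
    eigendecomposed; the smallest prefix of axes whose cumulative variance,
    over the positive eigenvalues, reaches ``cutoff`` is retained.  The
    ``sqrt_patristic`` metric takes the square root of patristic distances
    first (which makes the matrix exactly Euclidean-embeddable).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    for node in tree.preorder():
        if node.parent is not None and not (node.duration or 0) > 0:
            raise TreeError("pco_eigenvectors requires positive branch durations")
    D = tree.patristic_distances()
    taxa = list(D.index)
    d = D.to_numpy(dtype=float)
    if metric == "sqrt_patristic":
        d = np.sqrt(d)
    elif metric != "patristic":
        raise ValueError(f"unknown metric {metric!r}")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10 * max(eigval.max(), 1.0), 0.0)
    pos = eigval > tol
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    fractions = eigval / eigval.sum()
    n_keep = int(np.searchsorted(np.cumsum(fractions), cutoff - 1e-12) + 1)
    n_keep = min(n_keep, len(eigval))
    scores = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    cols = [f"PCO{i + 1}" for i in range(n_keep)]
    return PcoAxes(
        scores=pd.DataFrame(scores, index=taxa, columns=cols),
        eigenvalues=eigval,
        variance_fractions=fractions,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------

def _pic_operator(tree: TimeTree) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Linear operator of Felsenstein's contrasts.

    Returns ``(C, W, tips)`` where the i-th standardized contrast of data x
    (in tip order ``tips``) is ``(C @ x)[i]`` and node working values are
    ``W @ x`` (rows in postorder over internal nodes).  The operator depends
    only on topology and branch durations, so contrasts of permuted or
    simulated data are matrix products.
    """
    tips = tree.tips()
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    weights: dict[int, np.ndarray] = {}
    lengths: dict[int, float] = {}
    contrasts: list[np.ndarray] = []
    node_rows: list[np.ndarray] = []
    for node in tree.postorder():
        d = node.duration
        if node.parent is not None and (d is None or d < 0):
            raise TreeError("pic requires non-negative branch durations")
        if node.is_tip:
            w = np.zeros(n)
            w[index[id(node)]] = 1.0
            weights[id(node)] = w
            lengths[id(node)] = float(d)
            continue
        if len(node.children) != 2:
            raise TreeError(
                "pic requires a fully bifurcating tree; resolve polytomies first"
            )
        c1, c2 = node.children
        v1, v2 = lengths[id(c1)], lengths[id(c2)]
        if v1 + v2 <= 0:
            raise TreeError("zero combined branch length at a contrast")
        contrasts.append((weights[id(c1)] - weights[id(c2)]) / np.sqrt(v1 + v2))
        w = (weights[id(c1)] / v1 + weights[id(c2)] / v2) / (1 / v1 + 1 / v2)
        weights[id(node)] = w
        node_rows.append(w)
        extra = v1 * v2 / (v1 + v2)
        lengths[id(node)] = (0.0 if node.parent is None else float(d)) + extra
    labels = [t.label for t in tips]
    return np.array(contrasts), np.array(node_rows), labels


def pic(tree: TimeTree, x: pd.Series | dict) -> pd.DataFrame:
    """Phylogenetically independent contrasts of one trait.

    Implements the pruning recursion: each contrast is the difference of the
    two daughter values divided by the square root of their summed branch
    lengths; the working value at the parent is the precision-weighted mean
    and its branch is lengthened by v1*v2/(v1+v2).  Returns n-1 rows with the
    standardized contrast and the ancestral working value.
    """
    C, W, tips = _pic_operator(tree)
    xv = _align_values(x, tips)
    return pd.DataFrame({"contrast": C @ xv, "node_value": W @ xv})


def _align_values(x, tips: list[str]) -> np.ndarray:
    if isinstance(x, dict):
        x = pd.Series(x)
    if isinstance(x, pd.Series):
        missing = [t for t in tips if t not in x.index]
        if missing:
            raise TreeError(f"missing tip value(s): {missing}")
        return x.loc[tips].to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float)
    if arr.shape[0] != len(tips):
        raise TreeError("value vector length does not match tip count")
    return arr


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

@dataclass
class KResult:
    """Blomberg's K with permutation significance.

    K compares the observed ratio of the ordinary to the phylogenetically
    corrected mean squared error with its expectation under Brownian motion
    on the same tree; K = 1 under pure Brownian motion, K < 1 for weaker and
    K > 1 for stronger than-Brownian similarity of relatives.
    """

    k: float
    observed_ratio: float
    expected_ratio: float
    p: Optional[float]
    permutations: int
    seed: Optional[int]

    def summary(self) -> str:
        ptxt = "n/a" if self.p is None else f"{self.p:.4g}"
        return (f"Blomberg's K = {self.k:.4g} "
                f"(p = {ptxt}, {self.permutations} permutations)")


def blomberg_k(
    tree: TimeTree,
    x,
    permutations: int = 999,
    seed: Optional[int] = None,
) -> KResult:
    """Blomberg's K and its permutation test.

    With V the Brownian-motion tip covariance (shared path lengths) and
    a = GLS mean: K = (MSE0/MSE) / E[MSE0/MSE | BM], where MSE0 is the raw
    mean squared deviation from a and MSE the V^-1-metric one, and
    E-ratio = (tr V - n / 1'V^-1 1)/(n-1).  Significance: tip values are
    permuted across the tree; the p value is the proportion of permutations
    whose phylogenetically corrected error (equivalently, variance of the
    independent contrasts) is at most the observed one, +1 convention.
    """
    tips = tree.tip_labels()
    xv = _align_values(x, tips)
    n = len(xv)
    if n < 4:
        raise TreeError("blomberg_k requires at least 4 tips")
    V = tree.shared_path_matrix().to_numpy(dtype=float)
    try:
        cho = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        raise TreeError(f"singular Brownian covariance: {exc}") from exc
    Vinv = linalg.cho_solve(cho, np.eye(n))
    one = np.ones(n)
    s1 = one @ Vinv @ one

    def _mse_pair(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # vals: n x m matrix of data columns
        a_hat = (one @ Vinv @ vals) / s1
        r = vals - a_hat
        mse0 = (r * r).sum(axis=0) / (n - 1)
        mse = (r * (Vinv @ r)).sum(axis=0) / (n - 1)
        return mse0, mse

    mse0, mse = _mse_pair(xv[:, None])
    observed = float(mse0[0] / mse[0])
    expected = float((np.trace(V) - n / s1) / (n - 1))
    k = observed / expected

    p = None
    if permutations >= 1:
        rng = np.random.default_rng(seed)
        perms = np.empty((n, permutations))
        for j in range(permutations):
            perms[:, j] = xv[rng.permutation(n)]
        _, mse_perm = _mse_pair(perms)
        p = float(((mse_perm <= mse[0]).sum() + 1) / (permutations + 1))
    return KResult(
        k=float(k), observed_ratio=observed, expected_ratio=expected,
        p=p, permutations=max(permutations, 0), seed=seed,
    )


# ---------------------------------------------------------------------------
# phylogenetic eigenvector regression
# ---------------------------------------------------------------------------

@dataclass
class PvrResult:
    """(Multivariate) phylogenetic eigenvector regression result.

    ``r2`` maps each response to its coefficient of determination;
    ``total_fraction`` is the pooled variance-explained fraction (for a
    single response it equals its R^2); the test is an F test for one
    response and Wilks' lambda with Rao's F approximation for several.
    """

    r2: pd.Series
    total_fraction: float
    statistic: float
    p: float
    coefficients: pd.DataFrame
    wilks_lambda: Optional[float] = None

    def summary(self) -> str:
        lines = [f"variance explained by phylogeny: {100 * self.total_fraction:.1f}%"]
        for name, val in self.r2.items():
            lines.append(f"  {name}: R^2 = {val:.3f}")
        stat = "F" if self.wilks_lambda is None else "Rao F"
        lines.append(f"{stat} = {self.statistic:.4g}, p = {self.p:.3g}")
        return "\n".join(lines)


def _design(axes: PcoAxes | pd.DataFrame) -> pd.DataFrame:
    scores = axes.scores if isinstance(axes, PcoAxes) else axes
    return scores.astype(float)


def pvr(axes: PcoAxes | pd.DataFrame, y) -> PvrResult:
    """Ordinary least squares of one response on the retained tree axes.

    The variance explained (R^2) estimates the fraction of the trait's
    interspecific variation attributable to phylogenetic relatedness.
    """
    X = _design(axes)
    yv = _align_values(y, list(X.index)) if not isinstance(y, np.ndarray) else y
    yv = np.asarray(yv, dtype=float)
    n, q = X.shape
    if q >= n:
        raise ValueError("more predictors than taxa minus one")
    Xd = np.column_stack([np.ones(n), X.to_numpy()])
    beta, *_ = np.linalg.lstsq(Xd, yv, rcond=None)
    resid = yv - Xd @ beta
    sst = float(((yv - yv.mean()) ** 2).sum())
    ssr = sst - float((resid ** 2).sum())
    if sst == 0:
        r2 = 0.0
        fstat, p = 0.0, 1.0
    else:
        r2 = max(ssr / sst, 0.0)
        df1, df2 = q, n - q - 1
        if df2 <= 0 or r2 >= 1 - 1e-14:
            fstat, p = np.inf, 0.0
        else:
            fstat = (r2 / df1) / ((1 - r2) / df2)
            p = float(stats.f.sf(fstat, df1, df2))
    name = y.name if isinstance(y, pd.Series) and y.name else "y"
    coef = pd.DataFrame(
        {name: beta}, index=["intercept"] + list(X.columns)
    )
    return PvrResult(
        r2=pd.Series({name: r2}),
        total_fraction=r2,
        statistic=float(fstat),
        p=float(p),
        coefficients=coef,
    )


def mpvr(axes: PcoAxes | pd.DataFrame, Y: pd.DataFrame) -> PvrResult:
    """Multivariate phylogenetic eigenvector regression.

    Each response column is regressed on the same retained axes; the pooled
    variance fraction is trace-based, sum(SSR_j)/sum(SST_j) (responses that
    are PC scores are already variance-weighted).  Overall significance is
    Wilks' lambda with Rao's F approximation.
    """
    X = _design(axes)
    if isinstance(Y, pd.DataFrame):
        Yv = Y.loc[list(X.index)].to_numpy(dtype=float)
        names = list(Y.columns)
    else:
        Yv = np.asarray(Y, dtype=float)
        names = [f"y{j + 1}" for j in range(Yv.shape[1])]
    n, q = X.shape
    m = Yv.shape[1]
    if m < 2:
        raise ValueError("mpvr needs at least two responses; use pvr")
    if q >= n:
        raise ValueError("more predictors than taxa minus one")

    Xd = np.column_stack([np.ones(n), X.to_numpy()])
    beta, *_ = np.linalg.lstsq(Xd, Yv, rcond=None)
    resid = Yv - Xd @ beta
    Yc = Yv - Yv.mean(axis=0)
    sst = (Yc ** 2).sum(axis=0)
    sse = (resid ** 2).sum(axis=0)
    ssr = sst - sse
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, np.clip(ssr / sst, 0, 1), 0.0)
    total = float(ssr.sum() / sst.sum())

    # Wilks' lambda: E = residual SSCP, H = model SSCP (about the mean)
    E = resid.T @ resid
    H = Yc.T @ Yc - E
    wilks = float(np.linalg.det(E) / np.linalg.det(E + H))
    p_pred = q
    mm = n - 1 - (p_pred + m + 1) / 2
    denom = p_pred ** 2 + m ** 2 - 5
    s = np.sqrt((p_pred ** 2 * m ** 2 - 4) / denom) if denom > 0 else 1.0
    df1 = p_pred * m
    df2 = mm * s - df1 / 2 + 1
    lam_s = wilks ** (1 / s)
    if df2 <= 0 or lam_s <= 0:
        fstat, p = np.inf, 0.0
    else:
        fstat = (1 - lam_s) / lam_s * df2 / df1
        p = float(stats.f.sf(fstat, df1, df2))
    coef = pd.DataFrame(beta, index=["intercept"] + list(X.columns), columns=names)
    return PvrResult(
        r2=pd.Series(r2, index=names),
        total_fraction=total,
        statistic=float(fstat),
        p=float(p),
        coefficients=coef,
        wilks_lambda=wilks,
    )
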
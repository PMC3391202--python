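"""Size adjustment of linear measurements and morphospace construction.

Linear cranial (or other) measurements confound size and shape.  Dividing each
specimen's measurements by their geometric mean yields dimensionless Mosimann
shape ratios that are invariant to isometric scaling; a principal component
analysis of those ratios, with every variable scaled to unit variance, is the
morphospace used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementTable",
    "Ordination",
    "geometric_mean",
    "mosimann_transform",
    "pca_morphospace",
    "species_centroids",
    "n_axes_for_variance",
]

META_COLUMNS = ("specimen", "species", "lineage")


@dataclass
class MeasurementTable:
    """Specimen-level measurement table.

    ``data`` holds the metadata columns ``specimen``, ``species``, ``lineage``
    followed by k positive measurement columns (all in the same length unit,
    or dimensionless after the Mosimann transform).
    """

    data: pd.DataFrame
    dimensionless: bool = False

    def __post_init__(self) -> None:
        for col in META_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"missing metadata column {col!r}")
            if self.data[col].astype(str).str.len().eq(0).any():
                raise ValueError(f"empty labels in column {col!r}")
        if len(self.variables) < 2:
            raise ValueError("need at least two measurement variables")
        vals = self.measurements.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("all measurements must be finite and positive")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def measurements(self) -> pd.DataFrame:
        return self.data[self.variables]

    @property
    def species(self) -> pd.Series:
        return self.data["species"]

    @property
    def lineage(self) -> pd.Series:
        return self.data["lineage"]

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path_or_buf, **kwargs) -> "MeasurementTable":
        return cls(pd.read_csv(path_or_buf), **kwargs)

    def to_csv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, index=False)


def geometric_mean(x) -> float:
    """Geometric mean, the k-th root of the product of k positive values.

    Computed in log space for numerical stability; carries the unit of the
    inputs.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0 or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("geometric mean requires positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def mosimann_transform(table: MeasurementTable) -> MeasurementTable:
    """Divide each specimen's measurements by its geometric mean.

    The resulting shape ratios are dimensionless, multiply to 1 within each
    specimen, and are invariant to rescaling any specimen's row by a positive
    constant (isometric size removal).
    """
    vals = table.measurements.to_numpy(dtype=float)
    gm = np.exp(np.mean(np.log(vals), axis=1, keepdims=True))
    out = table.data.copy()
    out[table.variables] = vals / gm
    return MeasurementTable(out, dimensionless=True)


@dataclass
class Ordination:
    """Scores, loadings and eigenvalues of a trait-space decomposition.

    ``scores`` is specimens x axes with the table's metadata as extra columns;
    ``loadings`` holds the orthonormal variable loadings (variables x axes);
    ``variance_fractions`` sum to 1 over all computed axes.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    center: np.ndarray = None
    scale: np.ndarray = None

    @property
    def axes(self) -> list[str]:
        return list(self.loadings.columns)

    def score_matrix(self, n_axes: Optional[int] = None) -> np.ndarray:
        cols = self.axes if n_axes is None else self.axes[:n_axes]
        return self.scores[cols].to_numpy(dtype=float)

    def summary(self) -> str:
        lines = ["axis  eigenvalue  %var  cum%"]
        cum = 0.0
        for name, ev, vf in zip(self.axes, self.eigenvalues, self.variance_fractions):
            cum += vf
            lines.append(f"{name:<5} {ev:10.4f} {100 * vf:5.1f} {100 * cum:5.1f}")
        return "\n".join(lines)


def n_axes_for_variance(variance_fractions, cutoff: float = 0.90) -> int:
    """Smallest number of leading axes whose cumulative variance >= cutoff."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    cum = np.cumsum(np.asarray(variance_fractions, dtype=float))
    return int(np.searchsorted(cum, cutoff - 1e-12) + 1)


def pca_morphospace(table: MeasurementTable, standardize: bool = True) -> Ordination:
    """Principal component analysis of the measurement table.

    With ``standardize`` (the default) every variable is scaled to unit
    variance, i.e. the decomposition is of the correlation matrix; computed by
    singular value decomposition of the centered/scaled data.  Axis signs
    follow a fixed convention — the largest-magnitude loading on each axis is
    positive — so results are reproducible across platforms.
    """
    X = table.measurements.to_numpy(dtype=float)
    n, k = X.shape
    center = X.mean(axis=0)
    Xc = X - center
    if standardize:
        scale = Xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = [v for v, s in zip(table.variables, Xc.std(axis=0, ddof=1)) if s == 0]
            raise ValueError(f"constant column(s) under standardization: {bad}")
        Xc = Xc / scale
    else:
        scale = np.ones(k)

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    # deterministic sign: largest-|loading| entry positive on each axis
    for a in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[a]))
        if Vt[a, i] < 0:
            Vt[a] *= -1
            U[:, a] *= -1

    names = [f"PC{i + 1}" for i in range(len(eig))]
    scores = pd.DataFrame(U * s, columns=names)
    for col in reversed(META_COLUMNS):
        scores.insert(0, col, table.data[col].to_numpy())
    loadings = pd.DataFrame(Vt.T, index=table.variables, columns=names)
    return Ordination(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig,
        variance_fractions=eig / eig.sum(),
        center=center,
        scale=scale,
    )


def species_centroids(ordination: Ordination, by: str = "species") -> pd.DataFrame:
    """Per-species (or per-lineage) mean scores: the tip data for all
    phylogenetic comparative analyses."""
    if by not in META_COLUMNS:
        raise ValueError(f"unknown grouping column {by!r}")
    counts = ordination.scores[by].value_counts()
    if (counts == 0).any():  # pragma: no cover - defensive
        raise ValueError("group with zero specimens")
    cent = ordination.scores.groupby(by, sort=True)[ordination.axes].mean()
    if by == "species":
        lin = ordination.scores.groupby(by, sort=True)["lineage"].agg(
            lambda s: s.mode().iloc[0]
        )
        cent.insert(0, "lineage", lin)
    return cent
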
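"""Linear discriminant analysis of shape variables with leave-one-out
jackknife validation.

Classification accuracy of prior lineage assignments from size-adjusted
measurements is assessed by refitting the discriminant model n times, leaving
out one specimen per fold and predicting it from the remaining n-1: the
prediction for each specimen is then unbiased by that specimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["LdaModel", "ConfusionTable", "lda_fit", "jackknife_classify",
           "accuracy_from_confusion"]


@dataclass
class LdaModel:
    """Shared-covariance Gaussian discriminant model.

    Classification is by maximum posterior under a multivariate normal model
    with per-group means and one pooled within-group covariance.
    """

    groups: list[str]
    priors: np.ndarray
    means: np.ndarray              # groups x k
    pooled_covariance: np.ndarray  # k x k
    _clf: LinearDiscriminantAnalysis = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        labels = self._clf.predict(np.atleast_2d(np.asarray(x, dtype=float)))
        return np.asarray(labels)

    def posterior(self, x) -> pd.DataFrame:
        p = self._clf.predict_proba(np.atleast_2d(np.asarray(x, dtype=float)))
        return pd.DataFrame(p, columns=list(self._clf.classes_))


def _resolve_priors(priors: str, labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    if priors == "proportional":
        counts = np.array([(labels == c).sum() for c in classes], dtype=float)
        return counts / counts.sum()
    if priors == "uniform":
        return np.full(len(classes), 1.0 / len(classes))
    raise ValueError(f"priors must be 'proportional' or 'uniform', got {priors!r}")


def lda_fit(x, groups: Sequence[str], priors: str = "proportional") -> LdaModel:
    """Fit the discriminant model.

    ``priors`` are proportional to group sizes by default (switchable to
    uniform).  Groups with a single specimen contribute their mean only and
    trigger a warning.  A near-singular pooled covariance is handled by the
    SVD solver.
    """
    X = np.asarray(x, dtype=float)
    y = np.asarray(groups)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    singletons = classes[counts < 2]
    if len(singletons):
        warnings.warn(
            f"group(s) with a single specimen contribute mean only: "
            f"{list(singletons)}", stacklevel=2,
        )
    pri = _resolve_priors(priors, y, classes)
    clf = LinearDiscriminantAnalysis(
        solver="svd", priors=pri, store_covariance=True
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*collinear.*")
        clf.fit(X, y)
    return LdaModel(
        groups=list(clf.classes_),
        priors=pri,
        means=clf.means_,
        pooled_covariance=clf.covariance_,
        _clf=clf,
    )


@dataclass
class ConfusionTable:
    """Cross-tabulation of prior classifications against predictions.

    Rows are prior groups, columns predicted groups; per-group accuracy is
    the proportion of that row falling on the diagonal.
    """

    counts: pd.DataFrame
    posteriors: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.counts.columns):
            # predictions can omit groups; align to the union
            all_groups = sorted(set(self.counts.index) | set(self.counts.columns))
            self.counts = self.counts.reindex(
                index=all_groups, columns=all_groups, fill_value=0
            )

    @property
    def group_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.counts.to_numpy().sum())

    @property
    def group_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.index)
        return diag / self.group_sizes

    def summary(self) -> str:
        lines = [self.counts.to_string(), ""]
        for g, acc in self.group_accuracy.items():
            lines.append(f"{g:<20} {acc:6.3f}  ({int(self.counts.loc[g, g])}/"
                         f"{int(self.group_sizes[g])})")
        lines.append(f"{'overall':<20} {self.overall_accuracy:6.3f}")
        return "\n".join(lines)


def accuracy_from_confusion(table: ConfusionTable, group: str) -> float:
    """Proportion of one prior group's specimens predicted correctly."""
    if group not in table.counts.index:
        raise KeyError(f"unknown group {group!r}")
    total = table.group_sizes[group]
    if total == 0:
        raise ValueError(f"group {group!r} has no specimens")
    return float(table.counts.loc[group, group] / total)


def jackknife_classify(
    x, groups: Sequence[str], priors: str = "proportional"
) -> ConfusionTable:
    """Leave-one-out cross-validated classification.

    The full model is refit for every fold (no downdating shortcut).  If
    removing a specimen would empty its group, that fold is predicted among
    the remaining groups and flagged with a warning.  Per-specimen posterior
    probabilities of the held-out predictions are retained.
    """
    X = np.asarray(x, dtype=float)
    y = np.asarray(groups)
    n = len(y)
    classes = np.unique(y)
    if n < len(classes) + 2:
        raise ValueError("too few specimens for leave-one-out validation")

    predictions = np.empty(n, dtype=object)
    post_rows = []
    emptied: set[str] = set()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*single specimen.*")
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if (y[mask] == y[i]).sum() == 0:
                emptied.add(y[i])
            model = lda_fit(X[mask], y[mask], priors=priors)
            predictions[i] = model.predict(X[i])[0]
            post = model.posterior(X[i]).iloc[0]
            post_rows.append(post)
    if emptied:
        warnings.warn(
            f"fold removal emptied group(s) {sorted(emptied)}; those specimens "
            "were predicted among the remaining groups", stacklevel=2,
        )

    counts = pd.crosstab(
        pd.Series(y, name="prior"), pd.Series(predictions, name="predicted")
    )
    counts = counts.reindex(index=classes, columns=classes, fill_value=0)
    posteriors = pd.DataFrame(post_rows).reset_index(drop=True).fillna(0.0)
    posteriors.insert(0, "prior", y)
    posteriors.insert(1, "predicted", predictions)
    return ConfusionTable(counts=counts, posteriors=posteriors)
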
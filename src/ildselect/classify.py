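"""Two-group linear discriminant analysis with leave-one-out validation.

The classifier is the standard equal-covariance Gaussian discriminant:
group means and a pooled within-group covariance (divisor n - 2) define
Mahalanobis distances D^2_g, and the posterior probability of the target
(second-level) group is

    PP = pi_T exp(-D^2_T / 2) / sum_g pi_g exp(-D^2_g / 2).

Priors default to equal, the forensic convention (with balanced groups
equal and proportional priors coincide).  Leave-one-out cross-validation
refits the full model (means *and* pooled covariance) for every left-out
case.  Typicality of a case in a group is the upper-tail chi-squared
probability (p degrees of freedom) of its Mahalanobis distance -- low
values flag atypical cases even when they are confidently classified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "DiscriminantModel",
    "ClassificationReport",
    "fit_lda",
    "posterior",
    "loo_cv",
    "typicality",
]

INDETERMINATE = "indeterminate"


@dataclass
class DiscriminantModel:
    """Fitted two-group LDA: group means, pooled covariance and priors."""

    group_means: np.ndarray  # (2, p), mm
    pooled_cov: np.ndarray  # (p, p)
    priors: np.ndarray  # (2,), sums to 1
    predictor_names: list[str]
    group_labels: tuple[str, str]  # (start, target)

    @property
    def p(self) -> int:
        return self.group_means.shape[1]

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distances to both group means: (k, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], 2))
        chol = linalg.cho_factor(self.pooled_cov, lower=True)
        for g in range(2):
            diff = (X - self.group_means[g]).T
            z = linalg.cho_solve(chol, diff)
            out[:, g] = (diff * z).sum(axis=0)
        return out

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {
            "group_means": self.group_means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "priors": self.priors.tolist(),
            "predictor_names": list(self.predictor_names),
            "group_labels": list(self.group_labels),
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "DiscriminantModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            group_means=np.asarray(doc["group_means"], dtype=float),
            pooled_cov=np.asarray(doc["pooled_cov"], dtype=float),
            priors=np.asarray(doc["priors"], dtype=float),
            predictor_names=[str(s) for s in doc["predictor_names"]],
            group_labels=(str(doc["group_labels"][0]), str(doc["group_labels"][1])),
        )


@dataclass
class ClassificationReport:
    """Confusion table and accuracy summary of a cross-validated DA.

    ``bias`` is the signed difference first-group accuracy minus
    second-group accuracy in percentage points (e.g. 92 and 87 -> +5, a
    first-group-favouring classifier).  ``average_accuracy`` is the mean of
    the two per-group accuracies.
    """

    confusion: pd.DataFrame  # rows true, cols predicted, integer counts
    per_group_accuracy: dict[str, float]  # percent
    average_accuracy: float  # percent
    bias: float  # percentage points, first minus second group
    per_individual: pd.DataFrame

    @classmethod
    def from_confusion(
        cls,
        confusion: pd.DataFrame,
        group_labels: tuple[str, str],
        per_individual: Optional[pd.DataFrame] = None,
    ) -> "ClassificationReport":
        lvl1, lvl2 = group_labels
        acc = {}
        for lvl in (lvl1, lvl2):
            total = confusion.loc[lvl].sum()
            acc[lvl] = 100.0 * confusion.loc[lvl, lvl] / total if total else float("nan")
        return cls(
            confusion=confusion,
            per_group_accuracy=acc,
            average_accuracy=(acc[lvl1] + acc[lvl2]) / 2.0,
            bias=acc[lvl1] - acc[lvl2],
            per_individual=per_individual
            if per_individual is not None
            else pd.DataFrame(),
        )

    def summary_row(self) -> pd.DataFrame:
        """Accuracy table in the conventional layout: one row per true sex
        with counts per predicted sex, plus average and bias columns."""
        lvl1, lvl2 = list(self.confusion.index)
        out = self.confusion.copy()
        out["Average"] = [self.average_accuracy, self.average_accuracy]
        out[f"{lvl1}-biased"] = [self.bias, self.bias]
        out.index.name = "Sex"
        return out


def fit_lda(
    X: np.ndarray,
    factor: Sequence[str],
    priors: str = "equal",
    predictor_names: Optional[Sequence[str]] = None,
    group_labels: Optional[tuple[str, str]] = None,
) -> DiscriminantModel:
    """Fit the two-group linear discriminant model.

    ``priors`` is ``'equal'`` (default) or ``'proportional'`` to group
    sizes.  The pooled within-group covariance uses divisor n - 2; a
    singular pooled covariance (e.g. duplicated predictors) raises with a
    suggestion to drop predictors.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an n x p matrix")
    factor = np.asarray(factor)
    if group_labels is None:
        uniq: list[str] = []
        for v in factor:
            if v not in uniq:
                uniq.append(v)
        if len(uniq) != 2:
            raise ValueError(f"factor must have exactly two levels, got {uniq}")
        group_labels = (str(uniq[0]), str(uniq[1]))
    masks = [factor == lvl for lvl in group_labels]
    counts = np.asarray([m.sum() for m in masks])
    if (counts < 2).any():
        raise ValueError("both groups need at least 2 individuals")
    n, p = X.shape
    means = np.stack([X[m].mean(axis=0) for m in masks])
    scatter = sum(
        (X[m] - means[g]).T @ (X[m] - means[g]) for g, m in enumerate(masks)
    )
    pooled = scatter / (n - 2)
    try:
        linalg.cho_factor(pooled)
    except linalg.LinAlgError:
        raise ValueError(
            "pooled within-group covariance is singular; "
            "use fewer (or non-collinear) predictors"
        ) from None
    if priors == "equal":
        pr = np.array([0.5, 0.5])
    elif priors == "proportional":
        pr = counts / counts.sum()
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")
    if predictor_names is None:
        predictor_names = [f"x{j + 1}" for j in range(p)]
    return DiscriminantModel(
        group_means=means,
        pooled_cov=pooled,
        priors=pr,
        predictor_names=list(predictor_names),
        group_labels=group_labels,
    )


def posterior(model: DiscriminantModel, x: np.ndarray) -> Union[float, np.ndarray]:
    """Posterior probability of the target (second) group for one or more
    predictor vectors; the two group posteriors sum to one."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    d2 = model.mahalanobis_sq(x)
    log_w = np.log(model.priors)[None, :] - 0.5 * d2
    log_w -= log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    pp = w[:, 1] / w.sum(axis=1)
    return float(pp[0]) if single else pp


def typicality(model: DiscriminantModel, x: np.ndarray, group: str) -> float:
    """Upper-tail chi-squared probability (p dof) of the squared
    Mahalanobis distance of ``x`` from the given group's mean."""
    if group not in model.group_labels:
        raise ValueError(f"unknown group {group!r}")
    g = model.group_labels.index(group)
    d2 = model.mahalanobis_sq(np.asarray(x, dtype=float))[0, g]
    return float(stats.chi2.sf(d2, df=model.p))


def loo_cv(
    X: np.ndarray,
    factor: Sequence[str],
    priors: str = "equal",
    individual_ids: Optional[Sequence[str]] = None,
    predictor_names: Optional[Sequence[str]] = None,
    group_labels: Optional[tuple[str, str]] = None,
) -> ClassificationReport:
    """Leave-one-out cross-validated classification report.

    Every case is classified by a model refitted from scratch (means and
    pooled covariance) on the other n - 1 cases; PP > 0.5 predicts the
    target group, < 0.5 the start group, and exactly 0.5 is labelled
    indeterminate and counted as a misclassification (conservative
    forensic reporting).
    """
    X = np.asarray(X, dtype=float)
    factor = np.asarray(factor)
    n = X.shape[0]
    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(n)]
    full = fit_lda(X, factor, priors, predictor_names, group_labels)
    lvl1, lvl2 = full.group_labels

    rows = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if (factor[keep] == factor[i]).sum() < 2:
            raise ValueError(
                f"leaving out {individual_ids[i]!r} leaves its group too small"
            )
        sub = fit_lda(
            X[keep], factor[keep], priors, full.predictor_names, full.group_labels
        )
        pp = float(posterior(sub, X[i]))
        if pp > 0.5:
            pred = lvl2
        elif pp < 0.5:
            pred = lvl1
        else:
            pred = INDETERMINATE
        typ_group = pred if pred != INDETERMINATE else (lvl2 if pp >= 0.5 else lvl1)
        rows.append(
            {
                "individual": individual_ids[i],
                "true": str(factor[i]),
                "predicted": pred,
                "pp_target": pp,
                "typicality": typicality(sub, X[i], typ_group),
            }
        )
    per_individual = pd.DataFrame(rows)

    confusion = pd.DataFrame(0, index=[lvl1, lvl2], columns=[lvl1, lvl2], dtype=int)
    for r in rows:
        if r["predicted"] in (lvl1, lvl2):
            confusion.loc[r["true"], r["predicted"]] += 1
        else:  # indeterminate counts against the true group
            other = lvl2 if r["true"] == lvl1 else lvl1
            confusion.loc[r["true"], other] += 1
    return ClassificationReport.from_confusion(confusion, (lvl1, lvl2), per_individual)
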
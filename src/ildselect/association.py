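"""Per-ILD association with a two-group factor or covariate (ILDSR2 core).

Every interlandmark distance is scored by its coefficient of determination
(Rsq) against the factor: for a two-level factor this is the between-group
sum of squares over the total sum of squares, identical to the R^2 of a
one-predictor linear model on a group indicator; for a covariate it is the
squared Pearson correlation.  The top upper-percentile set (``r2tol``, e.g.
0.98 keeps the top 2%) is then stress-tested by within-group bootstrap:
each group is resampled with replacement at its own size, the scoring and
selection repeated, and the support of an observed top ILD is

    support = (1 + times re-selected) / (wg_rounds + 1),

so the observed analysis counts in both numerator and denominator (99
rounds give round percentages out of 100).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .landmark_io import FactorTable, LandmarkArray, SymmetryMap
from .superimposition import SuperimposedArray
from .ild_core import ILDMatrix, compute_ilds

__all__ = [
    "SelectionParams",
    "AssociationResult",
    "rsq_two_group",
    "rsq_covariate",
    "select_top",
    "ildsr2",
    "diagnostics",
    "plot_diagnostics",
]


@dataclass
class SelectionParams:
    """Tuning knobs for top-ILD selection and bootstrap support.

    ``r2tol`` is the upper percentile of the Rsq distribution defining the
    top set (0.98 -> top 2%); ``wg_rounds`` the number of within-group
    bootstrap resamples; ``canonical_only`` restricts scoring to canonical
    (mirror-deduplicated) columns instead of all q(q-1)/2.
    """

    r2tol: float = 0.98
    wg_rounds: int = 99
    seed: Optional[int] = None
    canonical_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.r2tol < 1.0:
            raise ValueError("r2tol must be in (0, 1)")
        if self.wg_rounds < 0:
            raise ValueError("wg_rounds must be >= 0")


@dataclass
class AssociationResult:
    """Output of :func:`ildsr2`.

    ``all_r2`` lists every scored ILD sorted by descending Rsq; ``top_set``
    is the selected set reduced to canonical ILD names, in rank order, with
    per-name bootstrap ``support`` in (0, 1].
    """

    all_r2: pd.DataFrame  # columns: name, r2 (+ column index), sorted desc
    top_set: list[str]
    support: dict[str, float]
    sample_ild: ILDMatrix
    n_boot: int
    top_columns: np.ndarray  # raw column indices of the observed top set
    degenerate: np.ndarray  # bool per scored column (constant ILD)


def rsq_two_group(values: Sequence[float], factor: Sequence[str]) -> float:
    """Between-group SS / total SS of ``values`` for a two-level factor.

    Constant values (total SS = 0) score 0 so the ranking stays total.
    """
    values = np.asarray(values, dtype=float)
    factor = np.asarray(factor)
    if values.ndim != 1 or len(values) != len(factor):
        raise ValueError("values and factor must be equal-length vectors")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    levels = np.unique(factor)
    if len(levels) != 2:
        raise ValueError(f"factor must have exactly two levels, got {list(levels)}")
    mask = factor == levels[1]
    r2, _ = _rsq_two_group_matrix(values[:, None], mask)
    return float(r2[0])


def _rsq_two_group_matrix(X: np.ndarray, mask_target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group Rsq per column; returns (r2, degenerate_mask)."""
    n = X.shape[0]
    n1 = int((~mask_target).sum())
    n2 = int(mask_target.sum())
    grand = X.mean(axis=0)
    m1 = X[~mask_target].mean(axis=0)
    m2 = X[mask_target].mean(axis=0)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    sst = ((X - grand) ** 2).sum(axis=0)
    # constant columns: a relative floor absorbs the rounding jitter of
    # summing identical floats, which would otherwise give 0/0 artefacts
    tol = n * (1e-9 * np.maximum(1.0, np.abs(grand))) ** 2
    degenerate = sst <= tol
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(degenerate, 0.0, ssb / np.where(degenerate, 1.0, sst))
    return np.clip(r2, 0.0, 1.0), degenerate


def rsq_covariate(values: Sequence[float], covariate: Sequence[float]) -> float:
    """Squared Pearson correlation of ``values`` with a real covariate."""
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if len(values) != len(covariate) or values.ndim != 1:
        raise ValueError("values and covariate must be equal-length vectors")
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant")
    r2, _ = _rsq_covariate_matrix(values[:, None], covariate)
    return float(r2[0])


def _rsq_covariate_matrix(X: np.ndarray, covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = covariate - covariate.mean()
    cc = (c**2).sum()
    if cc <= 0:
        raise ValueError("covariate is constant")
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    tol = len(X) * (1e-9 * np.maximum(1.0, np.abs(X.mean(axis=0)))) ** 2
    degenerate = sxx <= tol
    sxy = c @ Xc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(degenerate, 0.0, sxy**2 / (np.where(degenerate, 1.0, sxx) * cc))
    return np.clip(r2, 0.0, 1.0), degenerate


def top_k(n_scores: int, r2tol: float) -> int:
    """Size of the top set: ceil((1 - r2tol) * M) -- the rule that makes
    465 scores at r2tol=0.98 a 'top ten' (9.3 -> 10).  The product is
    rounded at 1e-9 first so binary float fuzz cannot inflate an exact
    integer boundary (e.g. 2% of 100 must give 2, not ceil(2.0000...2))."""
    return int(math.ceil(round((1.0 - r2tol) * n_scores, 9)))


def select_top(
    scores: Sequence[float],
    r2tol: float,
    names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Indices of the k = ceil((1-r2tol)*M) highest scores, in rank order.

    Scores are ranked at 1e-12 resolution so that exact ties (and ties up
    to summation rounding) are broken by ILD name ascending, then column
    index, making the selection deterministic under resampling.
    """
    scores = np.round(np.asarray(scores, dtype=float), 12)
    m = len(scores)
    if m < 1:
        raise ValueError("need at least one score")
    k = top_k(m, r2tol)
    if names is None:
        order = np.lexsort((np.arange(m), -scores))
    else:
        names = np.asarray(names, dtype=str)
        name_rank = np.empty(m, dtype=int)
        name_rank[np.argsort(names, kind="stable")] = np.arange(m)
        order = np.lexsort((np.arange(m), name_rank, -scores))
    return order[:k]


def _resolve_ilds(
    data: Union[LandmarkArray, SuperimposedArray, ILDMatrix],
    symmetry: Optional[SymmetryMap],
) -> ILDMatrix:
    if isinstance(data, ILDMatrix):
        return data
    return compute_ilds(data, symmetry)


def ildsr2(
    data: Union[LandmarkArray, SuperimposedArray, ILDMatrix],
    target: FactorTable,
    params: Optional[SelectionParams] = None,
    symmetry: Optional[SymmetryMap] = None,
) -> AssociationResult:
    """Score all ILDs against the factor/covariate, select the top
    percentile, and estimate bootstrap support for each observed top ILD.

    Factor mode resamples each group independently with replacement at its
    own size; covariate mode resamples whole (configuration, covariate)
    rows.  A top ILD counts as re-selected in a bootstrap round when any
    column of its mirror-redundancy class enters that round's own top-k
    set.  One root seed spawns independent per-round substreams, so results
    do not depend on evaluation order.
    """
    params = params or SelectionParams()
    ilds = _resolve_ilds(data, symmetry)
    y = target.aligned_to(ilds.individual_ids)

    canon = ilds.canonical_of()
    if params.canonical_only and ilds.canonical_mask is not None:
        cols = np.flatnonzero(ilds.canonical_mask)
    else:
        cols = np.arange(ilds.m)
    X = ilds.values[:, cols]
    names = np.asarray([ilds.names[j] for j in cols], dtype=object)

    if target.is_factor:
        lvl1, lvl2 = target.levels
        mask_target = y == lvl2
        g1 = np.flatnonzero(~mask_target)
        g2 = np.flatnonzero(mask_target)
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError("each group needs at least 2 individuals")
        scores, degenerate = _rsq_two_group_matrix(X, mask_target)
    else:
        scores, degenerate = _rsq_covariate_matrix(X, y)

    top_local = select_top(scores, params.r2tol, names)
    top_cols = cols[top_local]

    # observed top set reduced to canonical identity, preserving rank order
    top_canon: list[int] = []
    for j in top_cols:
        c = int(canon[j])
        if c not in top_canon:
            top_canon.append(c)

    hits = {c: 0 for c in top_canon}
    if params.wg_rounds == 0:
        warnings.warn(
            "wg_rounds=0: no bootstrap performed, all supports are 1/1",
            stacklevel=2,
        )
    else:
        children = np.random.SeedSequence(params.seed).spawn(params.wg_rounds)
        for child in children:
            rng = np.random.default_rng(child)
            if target.is_factor:
                rows = np.concatenate(
                    [
                        rng.choice(g1, size=len(g1), replace=True),
                        rng.choice(g2, size=len(g2), replace=True),
                    ]
                )
                boot_scores, _ = _rsq_two_group_matrix(X[rows], mask_target[rows])
            else:
                rows = rng.choice(len(y), size=len(y), replace=True)
                boot_scores, _ = _rsq_covariate_matrix(X[rows], y[rows])
            boot_top = cols[select_top(boot_scores, params.r2tol, names)]
            boot_canon = {int(canon[j]) for j in boot_top}
            for c in top_canon:
                if c in boot_canon:
                    hits[c] += 1

    denom = params.wg_rounds + 1
    support = {ilds.names[c]: (1 + hits[c]) / denom for c in top_canon}
    top_set = [ilds.names[c] for c in top_canon]

    name_rank = np.empty(len(cols), dtype=int)
    name_rank[np.argsort(names.astype(str), kind="stable")] = np.arange(len(cols))
    order = np.lexsort((np.arange(len(cols)), name_rank, -np.round(scores, 12)))
    all_r2 = pd.DataFrame(
        {
            "name": names[order],
            "r2": scores[order],
            "column": cols[order],
        }
    ).reset_index(drop=True)

    return AssociationResult(
        all_r2=all_r2,
        top_set=top_set,
        support=support,
        sample_ild=ilds,
        n_boot=params.wg_rounds,
        top_columns=top_cols,
        degenerate=degenerate,
    )


def diagnostics(
    data: Union[SuperimposedArray, ILDMatrix, LandmarkArray],
    target: FactorTable,
    mean_source: str = "direct",
    symmetry: Optional[SymmetryMap] = None,
) -> pd.DataFrame:
    """Per-canonical-ILD summary table: target/start ratio of group means,
    grand mean (mm), Rsq and per-group coefficients of variation.

    ``mean_source='direct'`` averages each ILD within each group;
    ``'form_consensus'`` instead averages the superimposed form coordinates
    per group and measures the ILDs of the two mean configurations -- this
    shortcut is only meaningful on superimposed form data and is refused on
    raw coordinates, where group-mean coordinates would contain spurious
    differences from digitization position and orientation.
    """
    if mean_source not in ("direct", "form_consensus"):
        raise ValueError("mean_source must be 'direct' or 'form_consensus'")
    if not target.is_factor:
        raise ValueError("diagnostics requires a two-level factor")
    if mean_source == "form_consensus":
        if isinstance(data, LandmarkArray) or not isinstance(data, SuperimposedArray):
            raise ValueError(
                "form-consensus means cannot be used when the data are raw "
                "coordinates; superimpose into form space first"
            )
        if data.scaled:
            raise ValueError("form-consensus means require unscaled (form-space) data")

    if isinstance(data, ILDMatrix):
        ilds = data
    else:
        ilds = compute_ilds(data, symmetry)
    y = target.aligned_to(ilds.individual_ids)
    lvl1, lvl2 = target.levels
    mask2 = y == lvl2

    X = ilds.values
    if mean_source == "direct":
        mean1 = X[~mask2].mean(axis=0)
        mean2 = X[mask2].mean(axis=0)
    else:
        assert isinstance(data, SuperimposedArray)
        cfg1 = data.coords[~mask2].mean(axis=0)
        cfg2 = data.coords[mask2].mean(axis=0)
        mean1 = _config_ilds(cfg1)
        mean2 = _config_ilds(cfg2)

    r2, _ = _rsq_two_group_matrix(X, mask2)
    sd1 = X[~mask2].std(axis=0, ddof=1)
    sd2 = X[mask2].std(axis=0, ddof=1)

    if ilds.canonical_mask is not None:
        keep = np.flatnonzero(ilds.canonical_mask)
    else:
        keep = np.arange(ilds.m)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pd.DataFrame(
            {
                "ratio_of_means": mean2[keep] / mean1[keep],
                "grand_mean_mm": 0.5 * (mean1[keep] + mean2[keep]),
                "r2": r2[keep],
                f"cv_{lvl1}": sd1[keep] / mean1[keep],
                f"cv_{lvl2}": sd2[keep] / mean2[keep],
            },
            index=pd.Index([ilds.names[j] for j in keep], name="ild"),
        )
    table.attrs["mean_source"] = mean_source
    table.attrs["levels"] = (lvl1, lvl2)
    return table


def _config_ilds(config: np.ndarray) -> np.ndarray:
    q = config.shape[0]
    a, b = np.triu_indices(q, k=1)
    return np.sqrt(((config[a] - config[b]) ** 2).sum(axis=1))


def plot_diagnostics(table: pd.DataFrame, r2tol: float = 0.98):
    """Four-panel diagnostic figure: ratio of group means and Rsq against
    the ILD grand mean, plus histograms of both.  Only meaningful for
    form-space data (see :func:`diagnostics`)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if table.attrs.get("mean_source") == "raw":
        raise ValueError("diagnostic plots are not meaningful on raw coordinates")
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    gm = table["grand_mean_mm"]
    axes[0, 0].scatter(gm, table["ratio_of_means"], s=10, alpha=0.6)
    axes[0, 0].axhline(1.0, color="grey", lw=0.8)
    axes[0, 0].set_xlabel("ILD grand mean (mm)")
    axes[0, 0].set_ylabel("target / start mean ratio")
    axes[0, 1].scatter(gm, table["r2"], s=10, alpha=0.6)
    cut = table["r2"].quantile(r2tol)
    axes[0, 1].axhline(cut, color="grey", lw=0.8)
    axes[0, 1].set_xlabel("ILD grand mean (mm)")
    axes[0, 1].set_ylabel("Rsq")
    axes[1, 0].hist(table["ratio_of_means"], bins=30)
    axes[1, 0].set_xlabel("target / start mean ratio")
    axes[1, 1].hist(table["r2"], bins=30)
    axes[1, 1].set_xlabel("Rsq")
    fig.tight_layout()
    return fig
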
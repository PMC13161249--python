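"""Thin-plate-spline posterior-probability contour plots over two ILDs.

The discriminant posterior probability of each training individual is
interpolated over the two-ILD data space with a 2D thin-plate spline
(kernel r^2 log r plus an affine part, optional ridge penalty lambda on the
kernel block; lambda may be chosen by generalized cross-validation).
Contour lines of the surface at 0.1 intervals turn the scatterplot into the
analogue of a topographic map: a new case is classified graphically by
where it falls relative to the 0.5 isoline, with the 0.2 / 0.8 isolines
marking the 80%-confidence boundaries for each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "ContourModel",
    "GridField",
    "fit_tps",
    "evaluate",
    "classify_new",
    "render_pp_plot",
]

CONTOUR_LEVELS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1)
_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-8, 4, 25)])[1:]  # gcv grid


@dataclass
class GridField:
    """Regular grid of interpolated posterior probabilities.

    ``values`` are clamped to [0, 1] for display and classification (a TPS
    can overshoot the data range); ``raw_values`` keep the unclamped
    surface for audit.
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    values: np.ndarray  # (ny, nx), clamped
    raw_values: np.ndarray

    def __post_init__(self) -> None:
        if not (np.diff(self.x_axis) > 0).all() or not (np.diff(self.y_axis) > 0).all():
            raise ValueError("grid axes must be strictly increasing")


@dataclass
class ContourModel:
    """Fitted thin-plate spline over an n x 2 training set."""

    train_points: np.ndarray  # (n, 2), mm
    train_pp: np.ndarray  # (n,), in [0, 1]
    weights: np.ndarray  # (n,) kernel weights
    affine: np.ndarray  # (3,): constant + two slopes
    lam: float
    bbox: tuple[tuple[float, float], tuple[float, float]]  # padded data range
    group_labels: tuple[str, str] = ("start", "target")
    gcv_lambdas: Optional[np.ndarray] = None
    gcv_scores: Optional[np.ndarray] = None


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """r^2 log(r) evaluated from squared distances, with K(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)  # r^2 log r = 0.5 r^2 log r^2
    return np.where(r2 > 0, out, 0.0)


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return _tps_kernel(d2)


def _solve_system(
    K: np.ndarray, P: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Solve the TPS block system; returns (weights, affine, fitted, trace
    of the influence matrix)."""
    n = K.shape[0]
    M = np.zeros((n + 3, n + 3))
    M[:n, :n] = K + lam * np.eye(n)
    M[:n, n:] = P
    M[n:, :n] = P.T
    rhs = np.zeros((n + 3, 1 + n))
    rhs[:n, 0] = y
    rhs[:n, 1:] = np.eye(n)
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        raise ValueError(
            "thin-plate system is singular (duplicate points?); "
            "use a smoothing lambda > 0"
        ) from None
    w, a = sol[:n, 0], sol[n:, 0]
    influence = K @ sol[:n, 1:] + P @ sol[n:, 1:]  # maps y -> fitted values
    fitted = K @ w + P @ a
    return w, a, fitted, float(np.trace(influence))


def fit_tps(
    points: np.ndarray,
    values: np.ndarray,
    lam: Union[float, str] = "gcv",
    group_labels: tuple[str, str] = ("start", "target"),
    bbox_pad: float = 0.05,
) -> ContourModel:
    """Fit the thin-plate spline surface to scattered (x, y, PP) data.

    ``lam=0`` interpolates the training values exactly; ``lam='gcv'``
    (default, mirroring common smoothing practice) minimizes the
    generalized cross-validation score n * RSS / (n - tr A)^2 over a
    logarithmic lambda grid.  Duplicate points are refused: with
    conflicting values the surface is ill-posed, and even with equal values
    the lambda = 0 system is singular, so a lambda > 0 is advised.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an n x 2 array (two-ILD data space)")
    n = points.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points to fit a thin-plate spline")
    if values.shape != (n,):
        raise ValueError("values must match points")

    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) < n:
        for g in range(len(uniq)):
            vals = values[inverse == g]
            if np.ptp(vals) > 0:
                raise ValueError(
                    f"duplicate training points at {tuple(uniq[g])} with "
                    "conflicting values"
                )
        if not (isinstance(lam, str) or lam > 0):
            raise ValueError(
                "duplicate training points make lambda=0 singular; "
                "use a smoothing lambda > 0"
            )

    K = _kernel_matrix(points, points)
    P = np.column_stack([np.ones(n), points])

    gcv_lambdas = gcv_scores = None
    if isinstance(lam, str):
        if lam != "gcv":
            raise ValueError("lam must be a number or 'gcv'")
        gcv_lambdas = _LAMBDA_GRID.copy()
        gcv_scores = np.empty_like(gcv_lambdas)
        for i, l in enumerate(gcv_lambdas):
            _, _, fitted, tr = _solve_system(K, P, values, l)
            rss = float(((values - fitted) ** 2).sum())
            denom = max(n - tr, 1e-12)
            gcv_scores[i] = n * rss / denom**2
        lam = float(gcv_lambdas[int(np.argmin(gcv_scores))])
    else:
        lam = float(lam)
        if lam < 0:
            raise ValueError("lambda must be >= 0")

    w, a, _, _ = _solve_system(K, P, values, lam)

    mins = points.min(axis=0)
    maxs = points.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    lo = mins - bbox_pad * span
    hi = maxs + bbox_pad * span
    return ContourModel(
        train_points=points,
        train_pp=values,
        weights=w,
        affine=a,
        lam=lam,
        bbox=((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))),
        group_labels=group_labels,
        gcv_lambdas=gcv_lambdas,
        gcv_scores=gcv_scores,
    )


def evaluate_points(model: ContourModel, query: np.ndarray) -> np.ndarray:
    """Raw (unclamped) surface values at arbitrary query points."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    K = _kernel_matrix(query, model.train_points)
    P = np.column_stack([np.ones(len(query)), query])
    return K @ model.weights + P @ model.affine


def evaluate_grid(model: ContourModel, nx: int = 200, ny: int = 200) -> GridField:
    """Evaluate the surface on a regular grid over the padded data range."""
    (x0, x1), (y0, y1) = model.bbox
    x_axis = np.linspace(x0, x1, nx)
    y_axis = np.linspace(y0, y1, ny)
    xx, yy = np.meshgrid(x_axis, y_axis)
    raw = evaluate_points(model, np.column_stack([xx.ravel(), yy.ravel()]))
    raw = raw.reshape(ny, nx)
    return GridField(x_axis, y_axis, np.clip(raw, 0.0, 1.0), raw)


def evaluate(
    model: ContourModel, query: Optional[np.ndarray] = None, grid: tuple[int, int] = (200, 200)
) -> Union[float, np.ndarray, GridField]:
    """Surface value(s) at ``query`` points, or a :class:`GridField` over
    the padded bounding box when ``query`` is None."""
    if query is None:
        return evaluate_grid(model, *grid)
    query = np.asarray(query, dtype=float)
    single = query.ndim == 1
    vals = evaluate_points(model, query)
    return float(vals[0]) if single else vals


def _pp_band(pp: float) -> str:
    lo = min(int(np.floor(pp * 10)), 9)
    return f"{lo / 10:.1f}-{(lo + 1) / 10:.1f}"


def classify_new(
    model: ContourModel,
    new_points: np.ndarray,
    threshold: float = 0.5,
    ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Classify new cases from the interpolated surface.

    Returns one row per case with the clamped PP estimate, the predicted
    label (target above the threshold, start below, indeterminate exactly
    at it), the 0.1-wide PP confidence band the case falls in, a
    low-confidence flag (group-specific PP < 0.8) and an extrapolation flag
    for cases outside the convex hull of the training points.
    """
    new_points = np.atleast_2d(np.asarray(new_points, dtype=float))
    raw = evaluate_points(model, new_points)
    pp = np.clip(raw, 0.0, 1.0)
    start, target = model.group_labels
    try:
        hull = Delaunay(model.train_points)
        inside = hull.find_simplex(new_points) >= 0
    except QhullError:  # degenerate training set; fall back to the bbox
        (x0, x1), (y0, y1) = model.bbox
        inside = (
            (new_points[:, 0] >= x0)
            & (new_points[:, 0] <= x1)
            & (new_points[:, 1] >= y0)
            & (new_points[:, 1] <= y1)
        )
    if ids is None:
        ids = [f"case{i + 1}" for i in range(len(new_points))]
    rows = []
    for i in range(len(new_points)):
        p = float(pp[i])
        if p > threshold:
            label = target
        elif p < threshold:
            label = start
        else:
            label = "indeterminate"
        rows.append(
            {
                "individual": ids[i],
                "x": new_points[i, 0],
                "y": new_points[i, 1],
                "pp_raw": float(raw[i]),
                "pp": p,
                "label": label,
                "band": _pp_band(p),
                "low_confidence": max(p, 1.0 - p) < 0.8,
                "extrapolated": bool(~inside[i]),
            }
        )
    return pd.DataFrame(rows)


def render_pp_plot(
    model: ContourModel,
    train_labels: Optional[Sequence[str]] = None,
    new_points: Optional[np.ndarray] = None,
    new_labels: Optional[Sequence[str]] = None,
    show_grid: bool = False,
    grid_n: int = 200,
    xlabel: str = "ILD 1 (mm)",
    ylabel: str = "ILD 2 (mm)",
    path: Optional[str] = None,
):
    """Render the PP contour scatterplot; returns (figure, GridField).

    Training individuals are drawn as circles (start group) and squares
    (target group) filled on a pink-to-blue gradient proportional to the
    target PP; contour lines run 0.0-1.0 at 0.1 steps with the 0.5
    classification boundary emphasized in violet and the 0.2/0.8
    80%-confidence isolines highlighted in pink and blue.  Optional new
    cases are overplotted as green filled circles / orange filled squares.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if model.train_points.shape[1] != 2:
        raise ValueError(
            "a PP contour scatterplot needs exactly two ILD predictors"
        )
    field = evaluate_grid(model, grid_n, grid_n)
    cmap = LinearSegmentedColormap.from_list(
        "male_pp", ["#ff4fa3", "#e8e0ee", "#15218c"]
    )
    fig, ax = plt.subplots(figsize=(7, 6))
    cs = ax.contour(
        field.x_axis,
        field.y_axis,
        field.values,
        levels=CONTOUR_LEVELS,
        colors="0.55",
        linewidths=0.8,
    )
    ax.clabel(cs, fmt="%.1f", fontsize=7)
    for level, color, lw in ((0.5, "#8a2be2", 2.4), (0.2, "#ff4fa3", 1.8), (0.8, "#15218c", 1.8)):
        ax.contour(
            field.x_axis,
            field.y_axis,
            field.values,
            levels=[level],
            colors=[color],
            linewidths=lw,
        )
    start, target = model.group_labels
    if train_labels is None:
        train_labels = [start] * len(model.train_points)
    train_labels = np.asarray([str(v) for v in train_labels])
    for lvl, marker in ((start, "o"), (target, "s")):
        mask = train_labels == lvl
        if mask.any():
            ax.scatter(
                model.train_points[mask, 0],
                model.train_points[mask, 1],
                c=model.train_pp[mask],
                cmap=cmap,
                vmin=0.0,
                vmax=1.0,
                marker=marker,
                edgecolors="k",
                linewidths=0.4,
                s=36,
                label=lvl,
            )
    if new_points is not None:
        new_points = np.atleast_2d(np.asarray(new_points, dtype=float))
        if new_labels is None:
            new_labels = [start] * len(new_points)
        new_labels = np.asarray([str(v) for v in new_labels])
        for lvl, marker, color in ((start, "o", "#1a9e3c"), (target, "s", "#f08a00")):
            mask = new_labels == lvl
            if mask.any():
                ax.scatter(
                    new_points[mask, 0],
                    new_points[mask, 1],
                    marker=marker,
                    color=color,
                    edgecolors="k",
                    linewidths=0.5,
                    s=48,
                    label=f"new {lvl}",
                )
    if show_grid:
        ax.grid(True, which="both", lw=0.4, alpha=0.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig, field
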
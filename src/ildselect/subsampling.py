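"""Randomized-subsampling robustness experiment for top-ILD selection.

Repeatedly draw balanced subsamples (e.g. 50 + 50 out of 100 + 100, without
replacement within each group), run the bootstrap-supported top-ILD
selection on each, and record which canonical ILDs come out well supported
(bootstrap support at or above a threshold, default 50%).  Aggregating
across replicates measures how strongly the selection depends on the exact
composition of the sample; the final selection keeps ILDs supported in
*more than* a given fraction of the replicates (default: more than half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .landmark_io import FactorTable, LandmarkArray, SymmetryMap
from .superimposition import SuperimposedArray
from .ild_core import ILDMatrix
from .association import AssociationResult, SelectionParams, ildsr2, _resolve_ilds

__all__ = [
    "SubsampleParams",
    "SubsampleSummary",
    "run_subsample_experiment",
    "final_ild_selection",
]


@dataclass
class SubsampleParams:
    """Design of the randomized-subsampling experiment."""

    n_per_group: int
    n_reps: int = 100
    support_threshold: float = 0.5  # within-subsample bootstrap support, >=
    selection: SelectionParams = field(default_factory=SelectionParams)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.support_threshold <= 1.0:
            raise ValueError("support_threshold must be in (0, 1]")


@dataclass
class SubsampleSummary:
    """Per-canonical-ILD aggregation over the randomized subsamples.

    ``table`` is indexed by ILD name with columns ``n_supporting``,
    ``frequency`` (= n_supporting / n_reps), and median/min/max of the
    bootstrap support and of the observed Rsq across the supporting
    subsamples only.
    """

    table: pd.DataFrame
    n_reps: int
    params: SubsampleParams


def _aggregate(
    records: dict[str, list[tuple[float, float]]], n_reps: int
) -> pd.DataFrame:
    """Aggregate per-ILD (support, r2) pairs from supporting subsamples."""
    rows = []
    for name, pairs in records.items():
        supports = np.asarray([s for s, _ in pairs])
        r2s = np.asarray([r for _, r in pairs])
        rows.append(
            {
                "ild": name,
                "n_supporting": len(pairs),
                "frequency": len(pairs) / n_reps,
                "support_median": float(np.median(supports)),
                "support_min": float(supports.min()),
                "support_max": float(supports.max()),
                "r2_median": float(np.median(r2s)),
                "r2_min": float(r2s.min()),
                "r2_max": float(r2s.max()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "ild",
            "n_supporting",
            "frequency",
            "support_median",
            "support_min",
            "support_max",
            "r2_median",
            "r2_min",
            "r2_max",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["frequency", "ild"], ascending=[False, True]
        ).set_index("ild")
    else:
        table = table.set_index("ild")
    return table


def run_subsample_experiment(
    data: Union[LandmarkArray, SuperimposedArray, ILDMatrix],
    target: FactorTable,
    sub: SubsampleParams,
    symmetry: Optional[SymmetryMap] = None,
) -> SubsampleSummary:
    """Run :func:`ildsr2` on ``n_reps`` balanced random subsamples.

    Each replicate draws ``n_per_group`` individuals per group without
    replacement (replicates are independent draws, so they overlap), and
    records every canonical top ILD whose bootstrap support meets the
    threshold, together with that subsample's support and observed Rsq.
    """
    if not target.is_factor:
        raise ValueError("the subsampling experiment requires a two-level factor")
    ilds = _resolve_ilds(data, symmetry)
    y = target.aligned_to(ilds.individual_ids)
    lvl1, lvl2 = target.levels
    g1 = np.flatnonzero(y == lvl1)
    g2 = np.flatnonzero(y == lvl2)
    if sub.n_per_group > min(len(g1), len(g2)):
        raise ValueError(
            f"n_per_group={sub.n_per_group} exceeds smallest group size "
            f"{min(len(g1), len(g2))}"
        )

    records: dict[str, list[tuple[float, float]]] = {}
    root = np.random.SeedSequence(sub.seed)
    for child in root.spawn(sub.n_reps):
        rng = np.random.default_rng(child)
        rows = np.concatenate(
            [
                rng.choice(g1, size=sub.n_per_group, replace=False),
                rng.choice(g2, size=sub.n_per_group, replace=False),
            ]
        )
        sub_ilds = ilds.subset_rows(rows)
        sub_target = FactorTable(
            individual_ids=sub_ilds.individual_ids,
            factor=[str(v) for v in y[rows]],
            levels=(lvl1, lvl2),
        )
        params = SelectionParams(
            r2tol=sub.selection.r2tol,
            wg_rounds=sub.selection.wg_rounds,
            seed=int(rng.integers(2**31)),
            canonical_only=sub.selection.canonical_only,
        )
        res = ildsr2(sub_ilds, sub_target, params)
        r2_by_name = dict(zip(res.all_r2["name"], res.all_r2["r2"]))
        for name in res.top_set:
            support = res.support[name]
            if support >= sub.support_threshold:
                records.setdefault(name, []).append((support, float(r2_by_name[name])))

    return SubsampleSummary(
        table=_aggregate(records, sub.n_reps), n_reps=sub.n_reps, params=sub
    )


def final_ild_selection(
    summary: SubsampleSummary, freq_threshold: float = 0.5
) -> list[str]:
    """Canonical ILDs supported in strictly more than ``freq_threshold`` of
    the randomized subsamples, ordered by frequency descending then name."""
    table = summary.table
    selected = table[table["frequency"] > freq_threshold]
    if selected.empty:
        warnings.warn(
            "no ILD exceeded the subsample frequency threshold; "
            "selection is empty",
            stacklevel=2,
        )
        return []
    selected = selected.sort_values(
        ["frequency", "ild"], ascending=[False, True], key=None
    )
    return list(selected.index)
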
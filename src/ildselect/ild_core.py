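"""Enumeration and naming of interlandmark distances (ILDs).

q landmarks define q(q-1)/2 pairwise Euclidean distances.  On bilaterally
symmetric structures many of those are mirror images of each other (for
example alare_L--zygion_L versus alare_R--zygion_R, or the two cross-midline
alare--zygion distances) and therefore carry the same information once the
asymmetric component has been discarded.  Redundancy is identified
*structurally* from the symmetry map -- a pair {a, b} is redundant when its
mirror image {sigma(a), sigma(b)} is a lexicographically smaller pair -- so
the classification works on raw, unsymmetrized coordinates as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landmark_io import LandmarkArray, SymmetryMap, strip_side
from .superimposition import SuperimposedArray

__all__ = [
    "ILDMatrix",
    "ild_count",
    "compute_ilds",
    "classify_redundancy",
    "count_nonredundant",
    "render_name",
]


@dataclass
class ILDMatrix:
    """n x m matrix of interlandmark distances (mm) with pair bookkeeping.

    ``canonical_mask[j]`` marks the retained representative of each
    mirror-redundancy class; ``mirror_of[j]`` points at the canonical column
    of a redundant one (-1 where the column is itself canonical).
    """

    values: np.ndarray  # (n, m)
    pairs: list[tuple[int, int]]  # (a, b) with a < b, lexicographic order
    names: list[str]
    individual_ids: list[str]
    canonical_mask: Optional[np.ndarray] = None  # bool (m,)
    mirror_of: Optional[np.ndarray] = None  # int (m,), -1 = canonical

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def canonical_of(self) -> np.ndarray:
        """Canonical column index for every column (identity when no
        symmetry information is attached)."""
        m = self.m
        if self.mirror_of is None:
            return np.arange(m)
        out = np.arange(m)
        redundant = self.mirror_of >= 0
        out[redundant] = self.mirror_of[redundant]
        return out

    def subset_rows(self, rows: Sequence[int], ids: Optional[Sequence[str]] = None) -> "ILDMatrix":
        rows = np.asarray(rows, dtype=int)
        if ids is None:
            ids = [self.individual_ids[r] for r in rows]
        return ILDMatrix(
            values=self.values[rows],
            pairs=self.pairs,
            names=self.names,
            individual_ids=list(ids),
            canonical_mask=self.canonical_mask,
            mirror_of=self.mirror_of,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.individual_ids, columns=self.names)
        df.index.name = "individual"
        return df

    def pair_table(self) -> pd.DataFrame:
        rows = {
            "landmark_a": [a for a, _ in self.pairs],
            "landmark_b": [b for _, b in self.pairs],
            "name": self.names,
        }
        if self.canonical_mask is not None:
            rows["canonical"] = self.canonical_mask
            rows["mirror_of"] = self.mirror_of
        return pd.DataFrame(rows)

    def export_csv(self, values_path: str | Path, pairs_path: Optional[str | Path] = None) -> None:
        self.to_frame().to_csv(values_path)
        if pairs_path is not None:
            self.pair_table().to_csv(pairs_path, index=False)


def ild_count(q: int) -> int:
    """Number of pairwise distances among ``q`` landmarks: q(q-1)/2."""
    q = int(q)
    if q < 2:
        raise ValueError(f"need at least 2 landmarks, got q={q}")
    return q * (q - 1) // 2


def count_nonredundant(m_mid: int, p_pairs: int) -> int:
    """Number of mirror-distinct ILDs for ``m_mid`` midplane landmarks and
    ``p_pairs`` bilateral pairs.

    The classes are: midplane-midplane C(m,2); midplane-side m*p (left and
    right versions coincide); left-right of the same pair p (self-mirror);
    and distances between two different bilateral pairs, p*(p-1) (of the
    four raw combinations, two same-side and two cross-side, each mirror
    class keeps one representative).
    """
    m_mid, p_pairs = int(m_mid), int(p_pairs)
    if m_mid < 0 or p_pairs < 0:
        raise ValueError("landmark counts must be non-negative")
    if m_mid + 2 * p_pairs < 2:
        raise ValueError("need at least 2 landmarks in total")
    return (
        m_mid * (m_mid - 1) // 2
        + m_mid * p_pairs
        + p_pairs
        + p_pairs * (p_pairs - 1)
    )


def render_name(
    pair: tuple[int, int],
    smap: Optional[SymmetryMap],
    landmark_names: Sequence[str],
) -> str:
    """Human-readable ILD name: base names joined by ``-``.

    Side markers are dropped (after symmetrization the sides are
    interchangeable); a distance between two bilateral landmarks on the
    *same* side gets the suffix ``-ss`` to distinguish it from the
    cross-midline version, which carries no suffix.
    """
    a, b = pair
    if smap is None:
        return f"{landmark_names[a]}-{landmark_names[b]}"
    base_a = strip_side(landmark_names[a])
    base_b = strip_side(landmark_names[b])
    name = f"{base_a}-{base_b}"
    side_a = smap.side_of(a)
    side_b = smap.side_of(b)
    if side_a != "midplane" and side_b != "midplane" and side_a == side_b:
        name += "-ss"
    return name


def classify_redundancy(
    pairs: Sequence[tuple[int, int]], smap: SymmetryMap
) -> tuple[np.ndarray, np.ndarray]:
    """Mark the canonical representative of each mirror class of pairs.

    The mirror image of {a, b} is {sigma(a), sigma(b)} with sigma swapping
    left/right partners.  Self-mirror pairs are canonical; otherwise the
    lexicographically smaller pair of the two is canonical and the other
    points at it through ``mirror_of``.
    """
    sigma = smap.sigma()
    index = {tuple(p): j for j, p in enumerate(pairs)}
    m = len(pairs)
    canonical = np.ones(m, dtype=bool)
    mirror_of = np.full(m, -1, dtype=int)
    for j, (a, b) in enumerate(pairs):
        ma, mb = int(sigma[a]), int(sigma[b])
        mirrored = (ma, mb) if ma < mb else (mb, ma)
        if mirrored == (a, b):
            continue
        if mirrored < (a, b):
            canonical[j] = False
            mirror_of[j] = index[mirrored]
    return canonical, mirror_of


def compute_ilds(
    data: LandmarkArray | SuperimposedArray,
    smap: Optional[SymmetryMap] = None,
) -> ILDMatrix:
    """All pairwise Euclidean distances per individual, in lexicographic
    pair order, with mirror-redundancy classification when a symmetry map
    is supplied."""
    coords = np.asarray(data.coords, dtype=float)
    n, q, _ = coords.shape
    if q < 2:
        raise ValueError("need at least 2 landmarks")
    a_idx, b_idx = np.triu_indices(q, k=1)
    diffs = coords[:, a_idx, :] - coords[:, b_idx, :]
    values = np.sqrt((diffs**2).sum(axis=2))
    pairs = [(int(a), int(b)) for a, b in zip(a_idx, b_idx)]
    names = [render_name(p, smap, data.landmark_names) for p in pairs]
    canonical_mask = mirror_of = None
    if smap is not None:
        smap.validate_for(q)
        canonical_mask, mirror_of = classify_redundancy(pairs, smap)
    return ILDMatrix(
        values=values,
        pairs=pairs,
        names=names,
        individual_ids=list(data.individual_ids),
        canonical_mask=canonical_mask,
        mirror_of=mirror_of,
    )
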
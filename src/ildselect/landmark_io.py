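"""Readers and writers for landmark data, factor tables and symmetry maps.

Three on-disk formats are supported for landmark configurations:

* ``tps`` -- the classic morphometrics interchange format: one record per
  individual starting with an ``LM=`` (2D) or ``LM3=`` (3D) line, followed
  by one whitespace-separated coordinate line per landmark; an optional
  ``ID=`` line names the individual and ``SCALE=``/``IMAGE=`` lines are
  ignored.  TPS files carry no landmark names, so reading one assigns
  generated names (``lm1`` ...) unless names are supplied.
* ``csv_wide`` -- one row per individual, a leading ``individual`` column
  and one ``<landmark>_<axis>`` column per coordinate.
* ``csv_long`` -- one row per (individual, landmark) with columns
  ``individual, landmark, x, y[, z]``.

Coordinates are treated as millimetres throughout; no unit conversion is
performed.  Landmark order is the file order and is authoritative for all
downstream indexing (0-based internally).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_AXES = "xyz"

__all__ = [
    "LandmarkArray",
    "SymmetryMap",
    "FactorTable",
    "LandmarkParseError",
    "read_landmarks",
    "write_landmarks",
    "read_factor_table",
    "write_factor_table",
    "read_symmetry_map",
    "write_symmetry_map",
]


class LandmarkParseError(ValueError):
    """Raised when a landmark, factor or symmetry file cannot be parsed."""


@dataclass
class LandmarkArray:
    """A set of landmark configurations: ``coords[i, j, k]`` is coordinate
    ``k`` of landmark ``j`` on individual ``i`` (millimetres)."""

    coords: np.ndarray
    individual_ids: list[str]
    landmark_names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be a (n, q, dim) array")
        n, q, d = self.coords.shape
        if d not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {d}")
        if n < 1:
            raise ValueError("need at least one individual")
        if q < 3:
            raise ValueError("need at least three landmarks")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        self.individual_ids = [str(s) for s in self.individual_ids]
        self.landmark_names = [str(s) for s in self.landmark_names]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match coords")
        if len(self.landmark_names) != q:
            raise ValueError("landmark_names length does not match coords")
        if len(set(self.landmark_names)) != q:
            raise ValueError("landmark_names must be unique")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def q(self) -> int:
        return self.coords.shape[1]

    @property
    def dim(self) -> int:
        return self.coords.shape[2]


@dataclass
class SymmetryMap:
    """Partition of landmarks into midplane points and (left, right) pairs.

    Indices refer to positions in a :class:`LandmarkArray`'s landmark order.
    """

    midplane: list[int]
    pairs: list[tuple[int, int]]  # (left_index, right_index)

    def __post_init__(self) -> None:
        self.midplane = [int(i) for i in self.midplane]
        self.pairs = [(int(l), int(r)) for l, r in self.pairs]
        seen: set[int] = set()
        for i in self.midplane:
            if i in seen:
                raise ValueError(f"landmark index {i} assigned more than once")
            seen.add(i)
        for l, r in self.pairs:
            if l == r:
                raise ValueError(f"pair ({l}, {r}) has identical sides")
            for i in (l, r):
                if i in seen:
                    raise ValueError(f"landmark index {i} assigned more than once")
                seen.add(i)

    @property
    def q(self) -> int:
        return len(self.midplane) + 2 * len(self.pairs)

    def validate_for(self, q: int) -> None:
        indices = set(self.midplane)
        for l, r in self.pairs:
            indices.update((l, r))
        if indices != set(range(q)):
            raise ValueError(
                f"symmetry map covers {sorted(indices)} but data has q={q} landmarks"
            )

    def sigma(self) -> np.ndarray:
        """Mirror permutation: swaps left/right partners, fixes midplane."""
        perm = np.arange(self.q)
        for l, r in self.pairs:
            perm[l], perm[r] = r, l
        return perm

    def side_of(self, index: int) -> str:
        if index in self.midplane:
            return "midplane"
        for l, r in self.pairs:
            if index == l:
                return "left"
            if index == r:
                return "right"
        raise KeyError(index)


@dataclass
class FactorTable:
    """Per-individual grouping factor (two levels) or real covariate.

    Exactly one of ``factor``/``covariate`` is set.  For a factor, the level
    order matters: the first level is the "start" group and the second the
    "target" group of all downstream contrasts (e.g. females then males).
    """

    individual_ids: list[str]
    factor: Optional[list[str]] = None
    covariate: Optional[np.ndarray] = None
    levels: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(s) for s in self.individual_ids]
        if (self.factor is None) == (self.covariate is None):
            raise ValueError("exactly one of factor/covariate must be set")
        if self.factor is not None:
            self.factor = [str(v) for v in self.factor]
            if len(self.factor) != len(self.individual_ids):
                raise ValueError("factor length does not match individual_ids")
            if self.levels is None:
                uniq: list[str] = []
                for v in self.factor:
                    if v not in uniq:
                        uniq.append(v)
                if len(uniq) != 2:
                    raise ValueError(f"factor must have exactly 2 levels, got {uniq}")
                self.levels = (uniq[0], uniq[1])
            present = set(self.factor)
            for lev in self.levels:
                if lev not in present:
                    raise ValueError(f"factor level {lev!r} not present in data")
            if present - set(self.levels):
                raise ValueError("factor contains values outside its declared levels")
        else:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if self.covariate.ndim != 1 or len(self.covariate) != len(self.individual_ids):
                raise ValueError("covariate must be a vector matching individual_ids")
            if not np.isfinite(self.covariate).all():
                raise ValueError("covariate contains non-finite values")

    @property
    def is_factor(self) -> bool:
        return self.factor is not None

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        """Return factor labels / covariate values reordered to ``ids``."""
        lookup = {iid: k for k, iid in enumerate(self.individual_ids)}
        missing = [iid for iid in ids if iid not in lookup]
        if missing:
            raise ValueError(f"individuals missing from factor table: {missing[:5]}")
        if len(ids) != len(self.individual_ids):
            raise ValueError("factor table and landmark data differ in size")
        order = [lookup[iid] for iid in ids]
        if self.is_factor:
            return np.asarray([self.factor[k] for k in order], dtype=object)
        return self.covariate[order]


# ---------------------------------------------------------------------------
# landmark files


def read_landmarks(
    path: str | Path,
    format: str,
    landmark_names: Optional[Sequence[str]] = None,
) -> LandmarkArray:
    """Read a landmark file in ``tps``, ``csv_wide`` or ``csv_long`` dialect."""
    path = Path(path)
    if format == "tps":
        return _read_tps(path, landmark_names)
    if format == "csv_wide":
        return _read_csv_wide(path)
    if format == "csv_long":
        return _read_csv_long(path)
    raise ValueError(f"unknown landmark format {format!r}")


def write_landmarks(data: LandmarkArray, path: str | Path, format: str) -> None:
    """Write ``data`` so that :func:`read_landmarks` reproduces it."""
    path = Path(path)
    if format == "tps":
        _write_tps(data, path)
    elif format == "csv_wide":
        _write_csv_wide(data, path)
    elif format == "csv_long":
        _write_csv_long(data, path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def _read_tps(path: Path, landmark_names: Optional[Sequence[str]]) -> LandmarkArray:
    configs: list[np.ndarray] = []
    ids: list[Optional[str]] = []
    cur: Optional[list[list[float]]] = None
    cur_n = 0
    cur_dim = 0
    cur_id: Optional[str] = None

    def flush() -> None:
        nonlocal cur, cur_id
        if cur is None:
            return
        if len(cur) != cur_n:
            which = cur_id if cur_id is not None else f"record {len(configs) + 1}"
            raise LandmarkParseError(
                f"{path}: individual {which!r} declares {cur_n} landmarks "
                f"but has {len(cur)} coordinate lines"
            )
        configs.append(np.asarray(cur, dtype=float))
        ids.append(cur_id)
        cur, cur_id = None, None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = re.match(r"^(LM3?)\s*=\s*(\d+)$", line, flags=re.IGNORECASE)
            if m:
                flush()
                cur = []
                cur_n = int(m.group(2))
                cur_dim = 3 if m.group(1).upper() == "LM3" else 2
                continue
            if "=" in line and not _is_numeric_line(line):
                key, _, value = line.partition("=")
                if key.strip().upper() == "ID":
                    cur_id = value.strip()
                continue  # SCALE=, IMAGE=, ... ignored
            if cur is None:
                raise LandmarkParseError(f"{path}:{lineno}: coordinates before any LM= line")
            parts = line.split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise LandmarkParseError(
                    f"{path}:{lineno}: non-numeric coordinate {line!r}"
                ) from None
            if len(values) != cur_dim:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected {cur_dim} coordinates, got {len(values)}"
                )
            cur.append(values)
    flush()
    if not configs:
        raise LandmarkParseError(f"{path}: no landmark records found")
    shapes = {c.shape for c in configs}
    if len(shapes) != 1:
        bad = next(
            (ids[i] or f"record {i + 1}")
            for i, c in enumerate(configs)
            if c.shape != configs[0].shape
        )
        raise LandmarkParseError(
            f"{path}: ragged landmark counts across individuals (first offender: {bad!r})"
        )
    q = configs[0].shape[0]
    names = list(landmark_names) if landmark_names is not None else [f"lm{j + 1}" for j in range(q)]
    final_ids = [iid if iid is not None else f"ind{i + 1}" for i, iid in enumerate(ids)]
    return LandmarkArray(np.stack(configs), final_ids, names)


def _write_tps(data: LandmarkArray, path: Path) -> None:
    tag = "LM3" if data.dim == 3 else "LM"
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(data.n):
            fh.write(f"{tag}={data.q}\n")
            for row in data.coords[i]:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write(f"ID={data.individual_ids[i]}\n")


def _is_numeric_line(line: str) -> bool:
    try:
        [float(p) for p in line.split()]
        return True
    except ValueError:
        return False


def _read_csv_wide(path: Path) -> LandmarkArray:
    df = pd.read_csv(path, float_precision="round_trip")
    if "individual" not in df.columns:
        raise LandmarkParseError(f"{path}: csv_wide file needs an 'individual' column")
    coord_cols = [c for c in df.columns if c != "individual"]
    names: list[str] = []
    axes_seen: dict[str, list[str]] = {}
    for c in coord_cols:
        base, _, axis = c.rpartition("_")
        if not base or axis not in _AXES:
            raise LandmarkParseError(f"{path}: column {c!r} is not '<landmark>_<axis>'")
        if base not in axes_seen:
            axes_seen[base] = []
            names.append(base)
        axes_seen[base].append(axis)
    dims = {len(v) for v in axes_seen.values()}
    if len(dims) != 1:
        raise LandmarkParseError(f"{path}: inconsistent axis counts across landmarks")
    dim = dims.pop()
    ids = [str(v) for v in df["individual"]]
    coords = np.empty((len(df), len(names), dim))
    for j, name in enumerate(names):
        for k in range(dim):
            col = f"{name}_{_AXES[k]}"
            if col not in df.columns:
                raise LandmarkParseError(f"{path}: missing column {col!r}")
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().idxmax())
                raise LandmarkParseError(
                    f"{path}: non-numeric or missing coordinate for individual "
                    f"{ids[row]!r}, landmark {name!r}"
                )
            coords[:, j, k] = vals.to_numpy()
    return LandmarkArray(coords, ids, names)


def _write_csv_wide(data: LandmarkArray, path: Path) -> None:
    cols: dict[str, object] = {"individual": data.individual_ids}
    for j, name in enumerate(data.landmark_names):
        for k in range(data.dim):
            cols[f"{name}_{_AXES[k]}"] = data.coords[:, j, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def _read_csv_long(path: Path) -> LandmarkArray:
    df = pd.read_csv(path, float_precision="round_trip")
    base_cols = {"individual", "landmark", "x", "y"}
    if not base_cols.issubset(df.columns):
        raise LandmarkParseError(f"{path}: csv_long needs columns individual,landmark,x,y[,z]")
    dim = 3 if "z" in df.columns else 2
    axes = list(_AXES[:dim])
    ids = list(dict.fromkeys(str(v) for v in df["individual"]))
    names = list(dict.fromkeys(str(v) for v in df["landmark"]))
    index = {(str(r.individual), str(r.landmark)): r for r in df.itertuples()}
    coords = np.empty((len(ids), len(names), dim))
    for i, iid in enumerate(ids):
        for j, name in enumerate(names):
            row = index.get((iid, name))
            if row is None:
                raise LandmarkParseError(
                    f"{path}: missing coordinates for individual {iid!r}, landmark {name!r}"
                )
            for k, ax in enumerate(axes):
                v = getattr(row, ax)
                try:
                    v = float(v)
                except (TypeError, ValueError):
                    v = float("nan")
                if not np.isfinite(v):
                    raise LandmarkParseError(
                        f"{path}: non-numeric coordinate for individual {iid!r}, "
                        f"landmark {name!r} ({ax})"
                    )
                coords[i, j, k] = v
    return LandmarkArray(coords, ids, names)


def _write_csv_long(data: LandmarkArray, path: Path) -> None:
    rows = []
    for i, iid in enumerate(data.individual_ids):
        for j, name in enumerate(data.landmark_names):
            row: dict[str, object] = {"individual": iid, "landmark": name}
            for k in range(data.dim):
                row[_AXES[k]] = data.coords[i, j, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# factor tables


def read_factor_table(
    path: str | Path,
    column: Optional[str] = None,
    levels: Optional[tuple[str, str]] = None,
) -> FactorTable:
    """Read a per-individual CSV with an ``individual`` column plus one
    factor or covariate column (numeric columns become covariates)."""
    df = pd.read_csv(path)
    if "individual" not in df.columns:
        raise LandmarkParseError(f"{path}: factor table needs an 'individual' column")
    others = [c for c in df.columns if c != "individual"]
    if column is None:
        if len(others) != 1:
            raise LandmarkParseError(
                f"{path}: ambiguous factor table, specify one of {others}"
            )
        column = others[0]
    ids = [str(v) for v in df["individual"]]
    values = df[column]
    if pd.api.types.is_numeric_dtype(values):
        return FactorTable(ids, covariate=values.to_numpy(dtype=float))
    return FactorTable(ids, factor=[str(v) for v in values], levels=levels)


def write_factor_table(table: FactorTable, path: str | Path, column: str = "factor") -> None:
    values = table.factor if table.is_factor else table.covariate
    pd.DataFrame({"individual": table.individual_ids, column: values}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# symmetry maps


def read_symmetry_map(
    path: str | Path,
    landmark_names: Optional[Sequence[str]] = None,
) -> SymmetryMap:
    """Read a symmetry-map CSV with columns ``landmark, side[, pair_name]``.

    ``side`` is one of ``midplane``/``left``/``right``; left and right
    entries are paired by ``pair_name`` (defaulting to the landmark name
    with any trailing ``_L``/``_R`` marker stripped).  Row order defines the
    landmark indices unless ``landmark_names`` gives the authoritative order.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"landmark", "side"}.issubset(df.columns):
        raise LandmarkParseError(f"{path}: symmetry map needs columns landmark, side")
    file_names = [str(v) for v in df["landmark"]]
    if len(set(file_names)) != len(file_names):
        dup = next(n for n in file_names if file_names.count(n) > 1)
        raise LandmarkParseError(f"{path}: duplicate assignment for landmark {dup!r}")
    if landmark_names is None:
        order = {name: i for i, name in enumerate(file_names)}
    else:
        order = {str(name): i for i, name in enumerate(landmark_names)}
        missing = [n for n in file_names if n not in order]
        if missing:
            raise LandmarkParseError(f"{path}: unknown landmarks {missing[:5]}")
        uncovered = sorted(set(order) - set(file_names))
        if uncovered:
            raise LandmarkParseError(f"{path}: landmarks without a side: {uncovered[:5]}")

    midplane: list[int] = []
    by_pair: dict[str, dict[str, str]] = {}
    for row in df.itertuples():
        name = str(row.landmark)
        side = str(row.side).strip().lower()
        pair = str(getattr(row, "pair_name", "") or strip_side(name))
        if pair in ("nan", ""):
            pair = strip_side(name)
        if side == "midplane":
            midplane.append(order[name])
        elif side in ("left", "right"):
            slot = by_pair.setdefault(pair, {})
            if side in slot:
                raise LandmarkParseError(
                    f"{path}: two {side!r} entries for pair {pair!r} "
                    f"({slot[side]!r} and {name!r})"
                )
            slot[side] = name
        else:
            raise LandmarkParseError(f"{path}: invalid side {side!r} for {name!r}")
    pairs: list[tuple[int, int]] = []
    for pair, slot in by_pair.items():
        if set(slot) != {"left", "right"}:
            (side, name), = slot.items()
            raise LandmarkParseError(
                f"{path}: unpaired {side!r} entry {name!r} (pair {pair!r})"
            )
        pairs.append((order[slot["left"]], order[slot["right"]]))
    pairs.sort()
    return SymmetryMap(sorted(midplane), pairs)


def write_symmetry_map(
    smap: SymmetryMap, landmark_names: Sequence[str], path: str | Path
) -> None:
    rows = []
    for i in smap.midplane:
        rows.append({"landmark": landmark_names[i], "side": "midplane", "pair_name": ""})
    for l, r in smap.pairs:
        base = strip_side(landmark_names[l])
        rows.append({"landmark": landmark_names[l], "side": "left", "pair_name": base})
        rows.append({"landmark": landmark_names[r], "side": "right", "pair_name": base})
    out = pd.DataFrame(rows)
    out["__order"] = [
        {str(landmark_names[i]): i for i in range(len(landmark_names))}[n]
        for n in out["landmark"]
    ]
    out.sort_values("__order").drop(columns="__order").to_csv(path, index=False)


_SIDE_SUFFIX = re.compile(r"[_ ]?(L|R|l|r|left|right|Left|Right)$")


def strip_side(name: str) -> str:
    """Base name of a landmark with any trailing side marker removed."""
    if name.endswith("_L") or name.endswith("_R"):
        return name[:-2]
    m = _SIDE_SUFFIX.search(name)
    if m and ("_" in name[m.start():] or " " in name[m.start():]):
        return name[: m.start()]
    return name
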
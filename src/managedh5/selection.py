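"""Selections on datasets and groups.

A :class:`Selection` is the operand of all relationship mapping rules.  It
comes in three forms:

* ``axes`` — one selector per axis: a point index, a half-open range
  (``slice`` with start/stop), or an explicit index list;
* ``points`` — an explicit list of coordinate tuples (used for mapped
  multi-dimensional results);
* ``members`` — a set of member names of a group.

All indices are 0-based and all ranges half-open.
"""

from __future__ import annotations

import json
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .errors import SelectionBoundsError, SelectionError

__all__ = ["Selection", "parse_selection"]


def _norm_selector(sel):
    if isinstance(sel, (int, np.integer)):
        return int(sel)
    if isinstance(sel, slice):
        if sel.step not in (None, 1):
            raise SelectionError("range selections must have step 1")
        if sel.start is None or sel.stop is None:
            raise SelectionError("range selections must have explicit start and stop")
        return slice(int(sel.start), int(sel.stop))
    if isinstance(sel, (list, tuple, np.ndarray)):
        return tuple(int(i) for i in sel)
    raise SelectionError(f"invalid selector {sel!r}")


class Selection:
    """Immutable selection in one of the three forms (axes/points/members)."""

    __slots__ = ("kind", "selectors", "point_list", "names")

    def __init__(self, kind, selectors=None, point_list=None, names=None):
        self.kind = kind
        self.selectors = selectors
        self.point_list = point_list
        self.names = names

    # -- constructors ---------------------------------------------------------
    @classmethod
    def axes(cls, selectors) -> "Selection":
        if isinstance(selectors, (int, np.integer, slice)):
            selectors = (selectors,)
        return cls("axes", selectors=tuple(_norm_selector(s) for s in selectors))

    @classmethod
    def points(cls, pts: Iterable[Sequence[int]]) -> "Selection":
        return cls(
            "points",
            point_list=tuple(tuple(int(i) for i in p) for p in pts),
        )

    @classmethod
    def members(cls, names: Iterable[str]) -> "Selection":
        return cls("members", names=tuple(str(n) for n in names))

    @classmethod
    def from_indices(cls, indices) -> "Selection":
        """1-D selection from a sequence of indices; a contiguous ascending
        run is emitted as a half-open range, anything else as a list."""
        idx = [int(i) for i in indices]
        if len(idx) >= 1 and all(b - a == 1 for a, b in zip(idx, idx[1:])):
            return cls.axes((slice(idx[0], idx[-1] + 1),))
        return cls.axes((tuple(idx),))

    @classmethod
    def from_points(cls, pts) -> "Selection":
        """Deduplicated, ascending selection from coordinate tuples.

        1-tuples collapse to a 1-D axes selection (range when contiguous).
        """
        uniq = sorted(set(tuple(int(i) for i in p) for p in pts))
        if uniq and len(uniq[0]) == 1:
            return cls.from_indices([p[0] for p in uniq])
        return cls.points(uniq)

    # -- basic queries --------------------------------------------------------
    @property
    def ndim(self):
        if self.kind == "axes":
            return len(self.selectors)
        if self.kind == "points":
            return len(self.point_list[0]) if self.point_list else None
        return None

    def is_empty(self) -> bool:
        if self.kind == "axes":
            for s in self.selectors:
                if isinstance(s, slice) and s.stop <= s.start:
                    return True
                if isinstance(s, tuple) and len(s) == 0:
                    return True
            return False
        if self.kind == "points":
            return len(self.point_list) == 0
        return len(self.names) == 0

    # -- resolution -----------------------------------------------------------
    @staticmethod
    def _axis_indices(sel, length: int) -> np.ndarray:
        if isinstance(sel, int):
            idx = np.array([sel])
        elif isinstance(sel, slice):
            if sel.start < 0 or sel.stop > length:
                raise SelectionBoundsError(
                    f"range [{sel.start}, {sel.stop}) out of bounds for axis of "
                    f"length {length}"
                )
            return np.arange(sel.start, max(sel.stop, sel.start))
        else:
            idx = np.asarray(sel, dtype=np.int64).reshape(-1)
        if idx.size and (idx.min() < 0 or idx.max() >= length):
            raise SelectionBoundsError(
                f"index selection out of bounds for axis of length {length}"
            )
        return idx

    def axis_indices(self, axis: int, length: int) -> np.ndarray:
        """Resolved (bounds-checked) indices selected along one axis."""
        if self.kind != "axes":
            raise SelectionError("axis_indices requires an axes-form selection")
        return self._axis_indices(self.selectors[axis], length)

    def positions(self, shape: Sequence[int]) -> List[Tuple[int, ...]]:
        """All selected positions as coordinate tuples (cartesian product of
        the per-axis index sets for axes form)."""
        if self.kind == "points":
            for p in self.point_list:
                for c, n in zip(p, shape):
                    if c < 0 or c >= n:
                        raise SelectionBoundsError(
                            f"point {p} out of bounds for shape {tuple(shape)}"
                        )
            return list(self.point_list)
        if self.kind != "axes":
            raise SelectionError("positions requires an axes- or points-form selection")
        if len(self.selectors) > len(shape):
            raise SelectionError(
                f"selection has {len(self.selectors)} axes but object has rank "
                f"{len(shape)}"
            )
        per_axis = [
            self._axis_indices(s, n) for s, n in zip(self.selectors, shape)
        ]
        grids = np.meshgrid(*per_axis, indexing="ij") if per_axis else []
        if not grids:
            return []
        stacked = np.stack([g.reshape(-1) for g in grids], axis=-1)
        return [tuple(int(c) for c in row) for row in stacked]

    def validate_bounds(self, shape: Sequence[int]) -> None:
        self.positions(shape)

    # -- data access ----------------------------------------------------------
    def read(self, dataset):
        """Read the selected values from an h5py dataset (or group for the
        members form)."""
        if self.kind == "members":
            return [dataset[name] for name in self.names]
        if self.kind == "points":
            if not self.point_list:
                return np.empty((0,), dtype=getattr(dataset, "dtype", float))
            return np.array([dataset[p] for p in self.point_list])
        if any(isinstance(s, tuple) for s in self.selectors):
            # h5py rejects unsorted/duplicated or multiple fancy indices;
            # fall back to numpy, which supports gather semantics
            arr = np.asarray(dataset[()])
            keys = []
            squeeze_axes = []
            for ax, s in enumerate(self.selectors):
                if isinstance(s, slice):
                    keys.append(np.arange(s.start, s.stop))
                elif isinstance(s, tuple):
                    keys.append(np.asarray(s, dtype=np.int64))
                else:
                    keys.append(np.asarray([s], dtype=np.int64))
                    squeeze_axes.append(ax)
            out = arr[np.ix_(*keys)] if keys else arr
            for ax in reversed(squeeze_axes):
                out = np.squeeze(out, axis=ax)
            return out
        key = tuple(self.selectors)
        return dataset[key]

    # -- serialization & comparison -------------------------------------------
    def to_obj(self):
        if self.kind == "axes":
            out = []
            for s in self.selectors:
                if isinstance(s, slice):
                    out.append({"start": s.start, "stop": s.stop})
                elif isinstance(s, tuple):
                    out.append(list(s))
                else:
                    out.append(s)
            return {"kind": "axes", "selectors": out}
        if self.kind == "points":
            return {"kind": "points", "points": [list(p) for p in self.point_list]}
        return {"kind": "members", "members": list(self.names)}

    def to_json(self, pretty: bool = False) -> str:
        return json.dumps(self.to_obj(), indent=2 if pretty else None)

    @classmethod
    def from_obj(cls, obj) -> "Selection":
        kind = obj.get("kind")
        if kind == "axes":
            sels = []
            for s in obj["selectors"]:
                if isinstance(s, dict):
                    sels.append(slice(s["start"], s["stop"]))
                elif isinstance(s, list):
                    sels.append(tuple(s))
                else:
                    sels.append(int(s))
            return cls.axes(tuple(sels))
        if kind == "points":
            return cls.points(obj["points"])
        if kind == "members":
            return cls.members(obj["members"])
        raise SelectionError(f"unknown selection kind {kind!r}")

    def __eq__(self, other):
        if not isinstance(other, Selection):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.selectors == other.selectors
            and self.point_list == other.point_list
            and self.names == other.names
        )

    def __repr__(self):
        if self.kind == "axes":
            return f"Selection.axes({self.selectors!r})"
        if self.kind == "points":
            return f"Selection.points({self.point_list!r})"
        return f"Selection.members({self.names!r})"


def _split_top_level(text: str) -> List[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def parse_selection(text: str) -> Selection:
    """Parse a command-line selection string.

    Per-axis selectors are comma-separated; each is ``i`` (a point),
    ``a:b`` (half-open range), or ``[i,j,k]`` (index list).  Example:
    ``"36,70"`` or ``"1:4,[0,2]"``.
    """
    selectors = []
    for part in _split_top_level(text.strip()):
        part = part.strip()
        if not part:
            raise SelectionError(f"empty selector in {text!r}")
        if part.startswith("["):
            if not part.endswith("]"):
                raise SelectionError(f"unterminated index list in {text!r}")
            body = part[1:-1].strip()
            items = [p for p in (q.strip() for q in body.split(",")) if p]
            selectors.append(tuple(int(i) for i in items))
        elif ":" in part:
            a, b = part.split(":", 1)
            selectors.append(slice(int(a), int(b)))
        else:
            selectors.append(int(part))
    return Selection.axes(tuple(selectors))
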
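"""Vector-reward comparisons: Pareto dominance, nondominated archives,
exact hypervolume, and the projection-distance penalty.

All rewards follow the maximization convention and, after reward shaping,
live in ``[0, 1]^d``; the hypervolume reference point therefore defaults to
the origin.  Dominance is the standard strict Pareto relation: ``x``
dominates ``y`` when no component is worse and at least one is strictly
better, so a point never dominates itself and fronts are well-formed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DimensionMismatchError, ReferenceNotDominatedError

Vector = np.ndarray


def _as_vec(x: Sequence[float] | Vector) -> Vector:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("a reward vector must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError("reward vectors must be finite")
    return v


def dominates(x: Sequence[float] | Vector, y: Sequence[float] | Vector) -> bool:
    """True iff ``x`` Pareto-dominates ``y`` (>= everywhere, > somewhere)."""
    xv, yv = _as_vec(x), _as_vec(y)
    if xv.shape != yv.shape:
        raise DimensionMismatchError(f"dimensions {xv.shape[0]} vs {yv.shape[0]}")
    return bool(np.all(xv >= yv) and np.any(xv > yv))


def pareto_front(points: Iterable[Sequence[float] | Vector]) -> Vector:
    """Distinct nondominated points among ``points``, as an (m, d) array.

    Points are sorted lexicographically descending and swept against the
    running archive, so the batch path and the incremental archive share no
    code with the all-pairs oracle used to test them.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.size == 0:
        raise ValueError("pareto_front requires at least one point")
    if arr.ndim != 2:
        raise DimensionMismatchError("points must share a common dimension")
    arr = np.unique(arr, axis=0)[::-1]  # lexicographic descending
    kept: list[Vector] = []
    for p in arr:
        if not any(dominates(q, p) for q in kept):
            kept = [q for q in kept if not dominates(p, q)]
            kept.append(p)
    order = np.lexsort(np.asarray(kept).T[::-1])
    return np.asarray(kept)[order]


def _nondominated_rows(arr: Vector) -> Vector:
    uniq = np.unique(arr, axis=0)
    keep = []
    for i, p in enumerate(uniq):
        ge = np.all(uniq >= p, axis=1)
        gt = np.any(uniq > p, axis=1)
        if not np.any(ge & gt):
            keep.append(i)
    return uniq[keep]


def hypervolume(
    points: Iterable[Sequence[float] | Vector] | Vector,
    z: Sequence[float] | Vector,
) -> float:
    """Lebesgue measure of the union of boxes ``[z, p]`` over front points.

    Exact for any dimension: sorted staircase in 2-D, recursive dimension
    sweep (slicing on the last objective) for d >= 3.  Every point must
    dominate the reference point component-wise.
    """
    zv = _as_vec(z)
    arr = np.atleast_2d(np.asarray(list(points), dtype=float))
    if arr.shape[1] != zv.shape[0]:
        raise DimensionMismatchError(
            f"points have dimension {arr.shape[1]}, reference {zv.shape[0]}"
        )
    if np.any(arr < zv):
        raise ReferenceNotDominatedError(
            "some point has a component below the reference point"
        )
    return _hv(_nondominated_rows(arr), zv)


def _hv(pts: Vector, z: Vector) -> float:
    if pts.size == 0:
        return 0.0
    d = z.shape[0]
    if d == 1:
        return float(pts[:, 0].max() - z[0])
    if d == 2:
        # staircase: walk x descending, add (x_i - x_{i+1}) * (ymax_i - z2)
        p = pts[np.argsort(-pts[:, 0])]
        total = 0.0
        ymax = z[1]
        for i, (x, y) in enumerate(p):
            nxt = p[i + 1, 0] if i + 1 < len(p) else z[0]
            ymax = max(ymax, y)
            total += (x - nxt) * (ymax - z[1])
        return float(total)
    # d >= 3: slice on the last objective (dimension sweep)
    order = np.argsort(-pts[:, -1])
    p = pts[order]
    levels = p[:, -1]
    total = 0.0
    for i in range(len(p)):
        lo = levels[i + 1] if i + 1 < len(p) else z[-1]
        height = levels[i] - lo
        if height <= 0:
            continue
        slab = _nondominated_rows(p[: i + 1, :-1])
        total += _hv(slab, z[:-1]) * height
    return float(total)


def projection_distance(
    r: Sequence[float] | Vector,
    front: Iterable[Sequence[float] | Vector] | Vector,
) -> float:
    """Penalty for dominated points: Euclidean distance to the nearest front
    point; zero when ``r`` is nondominated with respect to the front.

    The nearest-point form is O(|front|) per query, matching the method's
    emphasis on being cheap relative to repeated hypervolume evaluation.
    """
    rv = _as_vec(r)
    arr = np.atleast_2d(np.asarray(list(front), dtype=float))
    if arr.size == 0:
        raise ValueError("projection_distance requires a non-empty front")
    if arr.shape[1] != rv.shape[0]:
        raise DimensionMismatchError(
            f"front dimension {arr.shape[1]} vs point {rv.shape[0]}"
        )
    dominated = any(dominates(p, rv) for p in arr)
    if not dominated:
        return 0.0
    return float(np.sqrt(((arr - rv) ** 2).sum(axis=1)).min())


@dataclass
class ParetoArchive:
    """Incrementally maintained nondominated set with provenance links.

    ``members`` maps each front point (by key) to the ids of every generation
    record that achieved that exact reward vector; equal vectors from
    different molecules share one front point.
    """

    dim: int | None = None
    _points: list[Vector] = field(default_factory=list)
    members: dict[tuple[float, ...], set] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self._points)

    @property
    def points(self) -> Vector:
        if not self._points:
            return np.empty((0, self.dim or 0))
        return np.asarray(self._points)

    def is_dominated(self, r: Sequence[float] | Vector) -> bool:
        rv = _as_vec(r)
        return any(dominates(p, rv) for p in self._points)

    def add(self, r: Sequence[float] | Vector, record_id=None) -> bool:
        """Insert a reward vector; evict newly dominated points.

        Returns True when the vector joins the front.  The archive equals
        ``pareto_front`` of every vector ever inserted, at all times.
        """
        rv = _as_vec(r)
        if self.dim is None:
            self.dim = rv.shape[0]
        elif rv.shape[0] != self.dim:
            raise DimensionMismatchError(
                f"archive dimension {self.dim} vs point {rv.shape[0]}"
            )
        key = tuple(rv.tolist())
        if key in self.members:
            if record_id is not None:
                self.members[key].add(record_id)
            return True
        if self.is_dominated(rv):
            return False
        evicted = [p for p in self._points if dominates(rv, p)]
        if evicted:
            self._points = [p for p in self._points if not dominates(rv, p)]
            for p in evicted:
                self.members.pop(tuple(p.tolist()), None)
        self._points.append(rv)
        self.members[key] = set() if record_id is None else {record_id}
        return True

    def hypervolume(self, z: Sequence[float] | Vector) -> float:
        if not self._points:
            return 0.0
        return hypervolume(self._points, z)

    def projection_distance(self, r: Sequence[float] | Vector) -> float:
        return projection_distance(r, self._points)

    # -- export ------------------------------------------------------------

    def to_records(self) -> list[dict]:
        rows = []
        for p in sorted(self._points, key=lambda v: tuple(v)):
            key = tuple(p.tolist())
            rows.append(
                {
                    "components": list(key),
                    "member_ids": sorted(self.members.get(key, set())),
                }
            )
        return rows

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for rec in self.to_records():
            row = {f"r{i}": c for i, c in enumerate(rec["components"])}
            row["member_ids"] = ";".join(str(m) for m in rec["member_ids"])
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def update_front(
    front: ParetoArchive, r: Sequence[float] | Vector, record_id=None
) -> ParetoArchive:
    """Functional wrapper over :meth:`ParetoArchive.add`."""
    front.add(r, record_id)
    return front
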
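"""Varicose-fiber length density on a 40 µm box lattice.

The GPe of each parasagittal section is divided into axis-aligned square
boxes (default 0.04 mm) and every varicose fiber polyline contributes
the exact Euclidean length of its intersection with each box.  Segments
are first clipped to the section's region mask, then split at lattice
lines by parametric (Liang-Barsky style) clipping, so total grid mass
equals the mask-clipped varicose fiber length.

Boxes are half-open intervals [x, x+s) x [y, y+s): a point on a shared
edge belongs to the higher-index box only, which prevents double
counting.  The lattice origin is the floor, to box-size multiples, of
the bounding box of all section masks, so grids built from the same
dataset share one lattice regardless of channel.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .trace_io import Dataset, ValidationError

DEFAULT_BOX_SIZE = 0.04  # mm (40 um)


# ---------------------------------------------------------------------------
# single-segment clipping
# ---------------------------------------------------------------------------


def segment_length_in_box(p0, p1, box) -> float:
    """Length of a segment's intersection with a half-open square box.

    ``box`` is ``(x, y, size)`` for the square [x, x+size) x [y, y+size).
    Parametric clipping: the segment p0 + t (p1 - p0), t in [0, 1], is
    restricted to the slab of each axis and the surviving parameter
    interval scaled by the segment length.  (The half-open convention has
    no effect on lengths, only on index assignment of boundary points.)
    """
    x, y, s = float(box[0]), float(box[1]), float(box[2])
    if s <= 0:
        raise ValidationError("box size must be > 0")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for axis, lo in ((0, x), (1, y)):
        hi = lo + s
        if d[axis] == 0.0:
            if not (lo <= p0[axis] <= hi):
                return 0.0
            continue
        ta = (lo - p0[axis]) / d[axis]
        tb = (hi - p0[axis]) / d[axis]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 >= t1:
            return 0.0
    return float((t1 - t0) * np.linalg.norm(d))


# ---------------------------------------------------------------------------
# grid container
# ---------------------------------------------------------------------------


@dataclass
class DensityGrid:
    """Per-box varicose-fiber length for one channel of one mouse.

    ``table`` has columns ``section_index, row, col, length_mm`` with one
    entry per nonempty box; ``row`` indexes dv, ``col`` indexes rc, both
    relative to ``origin``.
    """

    channel: str
    box_size: float
    origin: tuple[float, float]  # (rc0, dv0) of the lattice
    table: pd.DataFrame
    section_ml: dict = field(default_factory=dict)  # section_index -> ml_center

    def total_mass(self) -> float:
        return float(self.table["length_mm"].sum())

    def entries(self) -> dict:
        """Mapping (section_index, row, col) -> length_mm."""
        return {
            (int(r.section_index), int(r.row), int(r.col)): float(r.length_mm)
            for r in self.table.itertuples()
        }

    def occupied(self, threshold: float = 0.0) -> set:
        """Box keys with length strictly above ``threshold``."""
        t = self.table[self.table["length_mm"] > threshold]
        return {
            (int(a), int(b), int(c))
            for a, b, c in zip(t["section_index"], t["row"], t["col"])
        }

    def box_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + (col + 0.5) * self.box_size,
            self.origin[1] + (row + 0.5) * self.box_size,
        )

    def section_matrix(self, section_index: int) -> tuple[np.ndarray, int, int]:
        """Dense matrix of one section's entries.

        Returns ``(matrix, row0, col0)`` where matrix[i, j] is the length
        in box (row0 + i, col0 + j); empty sections give a 0x0 matrix.
        """
        t = self.table[self.table["section_index"] == section_index]
        if len(t) == 0:
            return np.zeros((0, 0)), 0, 0
        r0, c0 = int(t["row"].min()), int(t["col"].min())
        mat = np.zeros((int(t["row"].max()) - r0 + 1, int(t["col"].max()) - c0 + 1))
        mat[t["row"].to_numpy() - r0, t["col"].to_numpy() - c0] = t[
            "length_mm"
        ].to_numpy()
        return mat, r0, c0


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------


def _polygon_crossing_params(segs: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Crossing parameters t of each segment with the polygon boundary.

    Returns an (n, k) padded array (invalid entries 1.0).  Edges are
    treated half-open at their first vertex so a crossing exactly at a
    polygon vertex is counted once.
    """
    n = len(segs)
    if n == 0 or len(vertices) == 0:
        return np.empty((n, 0))
    p = segs[:, :2]
    d = segs[:, 2:] - p
    q = vertices
    e = np.roll(vertices, -1, axis=0) - vertices
    # solve p + t d = q_j + u e_j for every (segment, edge) pair
    denom = d[:, 0:1] * e[None, :, 1] - d[:, 1:2] * e[None, :, 0]
    dq0 = q[None, :, 0] - p[:, 0:1]
    dq1 = q[None, :, 1] - p[:, 1:2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dq0 * e[None, :, 1] - dq1 * e[None, :, 0]) / denom
        u = (dq0 * d[:, 1:2] - dq1 * d[:, 0:1]) / denom
    valid = (
        np.isfinite(t) & np.isfinite(u)
        & (t > 0.0) & (t < 1.0) & (u >= 0.0) & (u < 1.0)
    )
    if not valid.any():
        return np.empty((n, 0))
    t = np.where(valid, t, 1.0)
    kmax = int(valid.sum(axis=1).max())
    return np.sort(t, axis=1)[:, :kmax] if kmax < t.shape[1] else t


def _split_segments_to_boxes(
    segs: np.ndarray, origin, s: float, mask_vertices: np.ndarray | None = None
):
    """Split segments at lattice lines (and an optional polygon mask).

    Fully vectorized: for every segment the crossing parameters with
    vertical and horizontal lattice lines — plus, when ``mask_vertices``
    is given, with the mask polygon's edges — are tabulated into a
    padded array and sorted; each sub-interval is assigned to the box
    containing its midpoint (half-open convention via floor of the
    midpoint), and sub-intervals whose midpoint falls outside the mask
    are discarded.  Returns (rows, cols, lengths).
    """
    if len(segs) == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    u0 = (segs[:, 0] - origin[0]) / s
    v0 = (segs[:, 1] - origin[1]) / s
    u1 = (segs[:, 2] - origin[0]) / s
    v1 = (segs[:, 3] - origin[1]) / s
    seg_len = np.hypot(segs[:, 2] - segs[:, 0], segs[:, 3] - segs[:, 1])

    fu0, fu1 = np.floor(u0), np.floor(u1)
    fv0, fv1 = np.floor(v0), np.floor(v1)
    ts = [np.zeros((len(segs), 1)), np.ones((len(segs), 1))]
    for a0, a1, f0, f1 in ((u0, u1, fu0, fu1), (v0, v1, fv0, fv1)):
        kmax = int(np.max(np.abs(f1 - f0))) if len(f0) else 0
        if kmax == 0:
            continue
        start = np.minimum(f0, f1) + 1.0
        count = np.abs(f1 - f0)
        j = np.arange(kmax)[None, :]
        lines = start[:, None] + j
        da = (a1 - a0)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (lines - a0[:, None]) / da
        t = np.where(j < count[:, None], t, 1.0)
        t = np.clip(np.nan_to_num(t, nan=1.0), 0.0, 1.0)
        ts.append(t)
    if mask_vertices is not None:
        ts.append(_polygon_crossing_params(segs, mask_vertices))
    tarr = np.sort(np.hstack(ts), axis=1)
    dt = np.diff(tarr, axis=1)
    tmid = 0.5 * (tarr[:, :-1] + tarr[:, 1:])
    mid_u = u0[:, None] + tmid * (u1 - u0)[:, None]
    mid_v = v0[:, None] + tmid * (v1 - v0)[:, None]
    cols = np.floor(mid_u).astype(int)
    rows = np.floor(mid_v).astype(int)
    lengths = dt * seg_len[:, None]
    keep = lengths > 0
    if mask_vertices is not None:
        from matplotlib.path import Path as MplPath

        mid_xy = np.column_stack(
            [
                (mid_u[keep] * s + origin[0]),
                (mid_v[keep] * s + origin[1]),
            ]
        )
        inside = MplPath(mask_vertices).contains_points(mid_xy)
        rows_k, cols_k, len_k = rows[keep], cols[keep], lengths[keep]
        return rows_k[inside], cols_k[inside], len_k[inside]
    return rows[keep], cols[keep], lengths[keep]


def build_grid(
    dataset: Dataset,
    channel: str,
    box_size: float = DEFAULT_BOX_SIZE,
    varicose_only: bool = True,
) -> DensityGrid:
    """Grid one channel's (by default varicose-only) fiber length.

    Segments are clipped to each section's region mask before boxing, so
    only the in-GPe part of a fiber is counted; box entries sum exactly to
    the mask-clipped polyline length.
    """
    if channel not in ("GFP", "RFP"):
        raise ValidationError(f"unknown channel: {channel!r}")
    if box_size <= 0:
        raise ValidationError("box_size must be > 0")

    mins = np.array(
        [sec.region_mask.min(axis=0) for sec in dataset.sections]
    )
    if len(mins) == 0:
        raise ValidationError("dataset has no sections")
    origin = tuple(np.floor(mins.min(axis=0) / box_size) * box_size)

    frames = []
    section_ml = {s.index: s.ml_center for s in dataset.sections}
    traces = dataset.traces_for(channel, varicose_only=varicose_only)
    by_section: dict[int, list] = {}
    for t in traces:
        by_section.setdefault(t.section_index, []).append(t.points)
    for sec in dataset.sections:
        pts = by_section.get(sec.index)
        if not pts:
            continue
        segs = np.vstack([np.hstack([p[:-1], p[1:]]) for p in pts])
        rows, cols, lengths = _split_segments_to_boxes(
            segs, origin, box_size, mask_vertices=sec.region_mask
        )
        if len(lengths) == 0:
            continue
        key = rows.astype(np.int64) * 2**31 + cols.astype(np.int64)
        uniq, inv = np.unique(key, return_inverse=True)
        mass = np.bincount(inv, weights=lengths)
        frames.append(
            pd.DataFrame(
                {
                    "section_index": sec.index,
                    "row": (uniq // 2**31).astype(int),
                    "col": (uniq % 2**31).astype(int),
                    "length_mm": mass,
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["section_index", "row", "col", "length_mm"]
        ).astype({"section_index": int, "row": int, "col": int,
                  "length_mm": float})
    return DensityGrid(
        channel=channel,
        box_size=float(box_size),
        origin=(float(origin[0]), float(origin[1])),
        table=table,
        section_ml=section_ml,
    )


def clipped_total_length(
    dataset: Dataset, channel: str, varicose_only: bool = True
) -> float:
    """Mask-clipped polyline length computed directly from whole polylines.

    Independent of the boxing path; used as the conservation reference.
    """
    total = 0.0
    by_section: dict[int, list] = {}
    for t in dataset.traces_for(channel, varicose_only=varicose_only):
        by_section.setdefault(t.section_index, []).append(t.points)
    for sec in dataset.sections:
        pts = by_section.get(sec.index)
        if not pts:
            continue
        poly = sec.polygon
        for p in pts:
            total += LineString(p).intersection(poly).length
    return float(total)


def grid_to_weighted_points(grid: DensityGrid):
    """One 3-D point per nonempty box, weighted by its fiber length.

    Points sit at box centers in-plane and at the section's ml center in
    depth; total weight equals the grid mass exactly.  Returns
    ``(points (n, 3), weights (n,))``.
    """
    t = grid.table
    if len(t) == 0:
        return np.empty((0, 3)), np.empty(0)
    rc = grid.origin[0] + (t["col"].to_numpy() + 0.5) * grid.box_size
    dv = grid.origin[1] + (t["row"].to_numpy() + 0.5) * grid.box_size
    ml = np.array([grid.section_ml[int(i)] for i in t["section_index"]])
    return np.column_stack([rc, dv, ml]), t["length_mm"].to_numpy().copy()


# ---------------------------------------------------------------------------
# heatmap export
# ---------------------------------------------------------------------------


def export_heatmap(
    grid: DensityGrid, path: str | Path, color_scale: float | None = None
) -> list[Path]:
    """Write one heatmap PNG + CSV matrix per nonempty section.

    Pseudocolor is a fixed linear map from 0 to ``color_scale`` (grid
    maximum when not given) mm per box.  The CSV holds the same matrix
    with row/col lattice indices, so it re-reads to the grid entries.
    Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if color_scale is not None:
        vmax = float(color_scale)
    elif len(grid.table):
        vmax = float(grid.table["length_mm"].max())
    else:
        vmax = 1.0

    sections = sorted(set(int(i) for i in grid.table["section_index"]))
    if not sections:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.set_axis_off()
        ax.set_title(f"{grid.channel}: empty grid")
        png = out / f"heatmap_{grid.channel}_empty.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        csv_path = out / f"heatmap_{grid.channel}_empty.csv"
        with open(csv_path, "w", newline="") as fh:
            csv.writer(fh).writerow(["section_index", "row", "col", "length_mm"])
        return [png, csv_path]

    for sec in sections:
        mat, r0, c0 = grid.section_matrix(sec)
        s = grid.box_size
        extent = [
            grid.origin[0] + c0 * s,
            grid.origin[0] + (c0 + mat.shape[1]) * s,
            grid.origin[1] + r0 * s,
            grid.origin[1] + (r0 + mat.shape[0]) * s,
        ]
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            mat, origin="lower", extent=extent, vmin=0.0, vmax=vmax,
            cmap="inferno", interpolation="nearest",
        )
        ax.set_xlabel("rostrocaudal (mm)")
        ax.set_ylabel("dorsoventral (mm)")
        ax.set_title(
            f"{grid.channel} varicose fiber length, section {sec} "
            f"(ml {grid.section_ml.get(sec, float('nan')):.2f} mm)"
        )
        fig.colorbar(im, ax=ax, label="length per box (mm)")
        png = out / f"heatmap_{grid.channel}_s{sec:04d}.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        written.append(png)

        csv_path = out / f"heatmap_{grid.channel}_s{sec:04d}.csv"
        t = grid.table[grid.table["section_index"] == sec]
        t[["section_index", "row", "col", "length_mm"]].to_csv(
            csv_path, index=False, float_format="%.12g"
        )
        written.append(csv_path)
    return written
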
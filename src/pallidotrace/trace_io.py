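"""Fiber-trace dataset model and on-disk format.

A dataset is organized as parasagittal sections: each section sits at a
mediolateral (ml) position, carries a region mask (the GPe outline as a
polygon in the rostrocaudal/dorsoventral plane), and holds 2-D fiber
polylines traced within it.  Somata are annotated in full 3-D atlas
coordinates.  All coordinates are millimeters from bregma: rc positive =
rostral, dv positive = dorsal, ml positive = lateral.

On disk a dataset is a directory::

    root/
      dataset.json     mouse_id + provenance
      sections.csv     index, ml_center_mm, thickness_mm, mask_file
      masks/*.csv      polygon vertices (rc_mm, dv_mm), closed implicitly
      somata.csv       soma_id, channel, rc_mm, dv_mm, ml_mm
      traces/*.swc     one SWC file per fiber trace

SWC files use the standard seven columns (id, type, x, y, z, radius,
parent).  Polyline vertices are written as axon nodes (type 2) with
x = rc, y = dv, z = the section's ml center.  Varicosities (axonal
boutons) are encoded as extra nodes of type 7 — the SWC custom-type
range — placed at their interpolated position on the polyline and
parented to the preceding polyline vertex; on read their arc-length
offsets are reconstructed from that geometry.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

CHANNELS = ("GFP", "RFP")

#: SWC node type used for polyline vertices (standard: axon).
SWC_AXON = 2
#: SWC node type repurposed for varicosity markers (custom-type range).
SWC_VARICOSITY = 7

_COORD_BOUND = 10.0  # mouse-brain sanity bound, mm from bregma


class FormatError(ValueError):
    """A file required by the on-disk layout is missing or malformed."""


class ValidationError(ValueError):
    """Data violate a dataset invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Point3:
    """A 3-D atlas position in mm from bregma (rc, dv, ml)."""

    rc: float
    dv: float
    ml: float

    def __post_init__(self) -> None:
        for name, v in (("rc", self.rc), ("dv", self.dv), ("ml", self.ml)):
            if not math.isfinite(v):
                raise ValidationError(f"non-finite {name} coordinate: {v!r}")
        if abs(self.rc) > _COORD_BOUND or abs(self.dv) > _COORD_BOUND:
            raise ValidationError(
                f"rc/dv out of sanity bounds (|x| <= {_COORD_BOUND} mm): "
                f"({self.rc}, {self.dv})"
            )
        if not 0.0 <= self.ml <= _COORD_BOUND:
            raise ValidationError(
                f"ml out of sanity bounds [0, {_COORD_BOUND}] mm: {self.ml}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.rc, self.dv, self.ml], dtype=float)


@dataclass
class SectionGeometry:
    """One parasagittal section: ml position, thickness, and GPe mask."""

    index: int
    ml_center: float
    region_mask: np.ndarray  # (n, 2) array of (rc, dv) vertices
    thickness: float = 0.02

    def __post_init__(self) -> None:
        self.region_mask = np.asarray(self.region_mask, dtype=float)
        if self.thickness <= 0:
            raise ValidationError(f"section {self.index}: thickness must be > 0")
        if self.region_mask.ndim != 2 or self.region_mask.shape[1] != 2:
            raise ValidationError(
                f"section {self.index}: region_mask must be an (n, 2) vertex array"
            )
        if len(self.region_mask) < 3:
            raise ValidationError(
                f"section {self.index}: region_mask needs >= 3 vertices"
            )
        poly = Polygon(self.region_mask)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError(
                f"section {self.index}: region_mask must be a simple polygon "
                "with nonzero area"
            )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.region_mask)


@dataclass
class FiberTrace:
    """A traced axon fiber: a 2-D polyline in one section's plane.

    ``varicosity_positions`` are arc-length offsets (mm) of boutons along
    the polyline; a trace with ``varicose=False`` carries none (the study
    traced some non-varicose GFP fibers, which are excluded from density
    quantification).
    """

    trace_id: str
    channel: str
    section_index: int
    points: np.ndarray  # (n, 2) array of (rc, dv)
    varicose: bool = True
    varicosity_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float)
    )

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.varicosity_positions = np.asarray(
            self.varicosity_positions, dtype=float
        )
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"trace {self.trace_id}: channel must be one of {CHANNELS}"
            )
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"trace {self.trace_id}: points must be an (n, 2) array"
            )
        if len(self.points) < 2:
            raise ValidationError(f"trace {self.trace_id}: needs >= 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(f"trace {self.trace_id}: non-finite vertex")
        steps = np.diff(self.points, axis=0)
        if np.any(np.all(steps == 0.0, axis=1)):
            raise ValidationError(
                f"trace {self.trace_id}: consecutive points must be distinct"
            )
        if not self.varicose and len(self.varicosity_positions) > 0:
            raise ValidationError(
                f"trace {self.trace_id}: non-varicose trace cannot carry "
                "varicosity positions"
            )
        if len(self.varicosity_positions) > 0:
            if np.any(np.diff(self.varicosity_positions) < 0):
                raise ValidationError(
                    f"trace {self.trace_id}: varicosity positions must be sorted"
                )
            total = self.length()
            tol = 1e-9 + 1e-9 * total
            if (
                self.varicosity_positions[0] < -tol
                or self.varicosity_positions[-1] > total + tol
            ):
                raise ValidationError(
                    f"trace {self.trace_id}: varicosity position outside "
                    f"[0, {total}]"
                )

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def length(self) -> float:
        """Total polyline arc length in mm."""
        return float(self.segment_lengths().sum())

    def point_at(self, s: float) -> np.ndarray:
        """Planar position at arc-length offset ``s`` (clamped to the ends)."""
        seglen = self.segment_lengths()
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = min(max(s, 0.0), cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seglen) - 1)
        t = 0.0 if seglen[i] == 0 else (s - cum[i]) / seglen[i]
        return self.points[i] + t * (self.points[i + 1] - self.points[i])


@dataclass(frozen=True)
class SomaRecord:
    """A labeled cell body with its 3-D atlas position."""

    soma_id: str
    channel: str
    position: Point3

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"soma {self.soma_id}: channel must be one of {CHANNELS}"
            )


@dataclass
class Dataset:
    """One mouse: sections, fiber traces, somata, and provenance."""

    mouse_id: str
    sections: list[SectionGeometry]
    traces: list[FiberTrace]
    somata: list[SomaRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        indices = [s.index for s in self.sections]
        if len(set(indices)) != len(indices):
            raise ValidationError("duplicate section indices")
        ordered = sorted(self.sections, key=lambda s: s.index)
        centers = [s.ml_center for s in ordered]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValidationError(
                "section ml_centers must strictly increase with index"
            )
        known = set(indices)
        missing = sorted(
            {t.trace_id for t in self.traces if t.section_index not in known}
        )
        if missing:
            raise ValidationError(
                f"traces reference unknown sections: {missing}"
            )

    def section_by_index(self, index: int) -> SectionGeometry:
        for s in self.sections:
            if s.index == index:
                return s
        raise KeyError(index)

    def traces_for(
        self, channel: str | None = None, varicose_only: bool = False
    ) -> list[FiberTrace]:
        out = self.traces
        if channel is not None:
            out = [t for t in out if t.channel == channel]
        if varicose_only:
            out = [t for t in out if t.varicose]
        return out

    def total_length(self, channel: str | None = None) -> float:
        return float(sum(t.length() for t in self.traces_for(channel)))


# ---------------------------------------------------------------------------
# atlas coordinates
# ---------------------------------------------------------------------------


def to_atlas_point(
    planar_point: Sequence[float], section: SectionGeometry
) -> Point3:
    """Lift an in-plane (rc, dv) vertex to 3-D using the section's ml center.

    Tracing is two-dimensional per section; depth within the section is not
    recorded, so every point of a section shares its ml coordinate.
    """
    rc, dv = float(planar_point[0]), float(planar_point[1])
    return Point3(rc=rc, dv=dv, ml=section.ml_center)


# ---------------------------------------------------------------------------
# adjacent-section superposition
# ---------------------------------------------------------------------------


def superimpose_adjacent(
    dataset: Dataset, pairing: Iterable[tuple[int, int]]
) -> Dataset:
    """Merge explicitly paired adjacent sections into single sections.

    The study traced GFP and RFP fibers in separate, physically adjacent
    20-µm sections and superimposed each pair in the parasagittal plane.
    Each pair becomes one section whose ml center is the midpoint of the
    pair's centers, whose mask is the polygon union, and whose thickness is
    the sum; traces of both members are reassigned to it.  Unpaired
    sections pass through unchanged.
    """
    pairing = list(pairing)
    by_index = {s.index: s for s in dataset.sections}
    used: set[int] = set()
    for a, b in pairing:
        if a == b:
            raise ValidationError(f"cannot pair section {a} with itself")
        if abs(a - b) != 1:
            raise ValidationError(
                f"sections {a} and {b} are not physically adjacent"
            )
        for idx in (a, b):
            if idx not in by_index:
                raise ValidationError(f"pairing references unknown section {idx}")
            if idx in used:
                raise ValidationError(f"section {idx} appears in two pairs")
            used.add(idx)

    remap: dict[int, int] = {}
    new_sections: list[SectionGeometry] = []
    for a, b in pairing:
        sa, sb = by_index[a], by_index[b]
        merged_index = min(a, b)
        union = unary_union([sa.polygon, sb.polygon])
        if union.geom_type != "Polygon":
            union = union.convex_hull  # disjoint masks: bridge conservatively
        new_sections.append(
            SectionGeometry(
                index=merged_index,
                ml_center=0.5 * (sa.ml_center + sb.ml_center),
                thickness=sa.thickness + sb.thickness,
                region_mask=np.asarray(union.exterior.coords)[:-1],
            )
        )
        remap[a] = merged_index
        remap[b] = merged_index
    for idx, sec in by_index.items():
        if idx not in used:
            new_sections.append(sec)
            remap[idx] = idx
    new_sections.sort(key=lambda s: s.index)

    new_traces = [
        replace(t, section_index=remap[t.section_index]) for t in dataset.traces
    ]
    return Dataset(
        mouse_id=dataset.mouse_id,
        sections=new_sections,
        traces=new_traces,
        somata=list(dataset.somata),
        provenance=dataset.provenance,
    )


# ---------------------------------------------------------------------------
# SWC read/write
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _trace_to_swc(trace: FiberTrace, ml_center: float) -> str:
    lines = [
        f"# trace_id: {trace.trace_id}",
        f"# channel: {trace.channel}",
        f"# section_index: {trace.section_index}",
        f"# varicose: {'true' if trace.varicose else 'false'}",
        "# columns: id type x(rc_mm) y(dv_mm) z(ml_mm) radius parent",
        f"# type {SWC_VARICOSITY} marks a varicosity on the parent vertex's segment",
    ]
    n = len(trace.points)
    for i, (rc, dv) in enumerate(trace.points):
        parent = -1 if i == 0 else i
        lines.append(
            f"{i + 1} {SWC_AXON} {_fmt(rc)} {_fmt(dv)} {_fmt(ml_center)} 0.5 {parent}"
        )
    seglen = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    node_id = n
    for s in trace.varicosity_positions:
        s_cl = min(max(float(s), 0.0), float(cum[-1]))
        i = int(np.searchsorted(cum, s_cl, side="right") - 1)
        i = min(i, len(seglen) - 1)
        t = 0.0 if seglen[i] == 0 else (s_cl - cum[i]) / seglen[i]
        pos = trace.points[i] + t * (trace.points[i + 1] - trace.points[i])
        node_id += 1
        lines.append(
            f"{node_id} {SWC_VARICOSITY} {_fmt(pos[0])} {_fmt(pos[1])} "
            f"{_fmt(ml_center)} 0.1 {i + 1}"
        )
    return "\n".join(lines) + "\n"


def _trace_from_swc(text: str, path: str = "<swc>") -> FiberTrace:
    meta: dict[str, str] = {}
    vertices: list[tuple[int, float, float]] = []
    varic: list[tuple[int, float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta.setdefault(key.strip(), val.strip())
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 SWC columns")
        try:
            node_id = int(parts[0])
            node_type = int(parts[1])
            x, y = float(parts[2]), float(parts[3])
            parent = int(parts[6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable SWC row") from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"{path}:{lineno}: non-finite coordinate")
        if node_type == SWC_VARICOSITY:
            varic.append((parent, x, y))
        else:
            vertices.append((node_id, x, y))
    for key in ("trace_id", "channel", "section_index"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}:' header")
    vertices.sort(key=lambda v: v[0])
    points = np.array([(x, y) for _, x, y in vertices], dtype=float)
    id_to_row = {node_id: row for row, (node_id, _, _) in enumerate(vertices)}

    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    positions = []
    for parent, x, y in varic:
        if parent not in id_to_row:
            raise ValidationError(
                f"{path}: varicosity node references unknown parent {parent}"
            )
        i = min(id_to_row[parent], len(seglen) - 1)
        positions.append(cum[i] + math.hypot(x - points[i, 0], y - points[i, 1]))
    positions.sort()
    return FiberTrace(
        trace_id=meta["trace_id"],
        channel=meta["channel"],
        section_index=int(meta["section_index"]),
        points=points,
        varicose=meta.get("varicose", "true").lower() == "true",
        varicosity_positions=np.array(positions, dtype=float),
    )


# ---------------------------------------------------------------------------
# dataset read/write
# ---------------------------------------------------------------------------


def write_dataset(dataset: Dataset, root_path: str | Path) -> None:
    """Write a dataset as the documented directory layout.

    Lossless for all coordinate fields at 12 significant digits.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(exist_ok=True)

    (root / "dataset.json").write_text(
        json.dumps(
            {"mouse_id": dataset.mouse_id, "provenance": dataset.provenance},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    with open(root / "sections.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "ml_center_mm", "thickness_mm", "mask_file"])
        for sec in sorted(dataset.sections, key=lambda s: s.index):
            mask_file = f"masks/mask_{sec.index:04d}.csv"
            w.writerow(
                [sec.index, _fmt(sec.ml_center), _fmt(sec.thickness), mask_file]
            )
            with open(root / mask_file, "w", newline="") as mh:
                mw = csv.writer(mh)
                mw.writerow(["rc_mm", "dv_mm"])
                for rc, dv in sec.region_mask:
                    mw.writerow([_fmt(rc), _fmt(dv)])

    with open(root / "somata.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["soma_id", "channel", "rc_mm", "dv_mm", "ml_mm"])
        for soma in dataset.somata:
            p = soma.position
            w.writerow(
                [soma.soma_id, soma.channel, _fmt(p.rc), _fmt(p.dv), _fmt(p.ml)]
            )

    if dataset.traces:
        (root / "traces").mkdir(exist_ok=True)
        by_index = {s.index: s for s in dataset.sections}
        for trace in dataset.traces:
            ml = by_index[trace.section_index].ml_center
            out = root / "traces" / f"{trace.trace_id}.swc"
            out.write_text(_trace_to_swc(trace, ml))


def read_dataset(root_path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(root_path)
    manifest = root / "sections.csv"
    if not manifest.exists():
        raise FormatError(f"missing section manifest: {manifest}")
    soma_path = root / "somata.csv"
    if not soma_path.exists():
        raise FormatError(f"missing soma table: {soma_path}")

    mouse_id, provenance = root.name, ""
    meta_path = root / "dataset.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        mouse_id = meta.get("mouse_id", mouse_id)
        provenance = meta.get("provenance", "")

    sections: list[SectionGeometry] = []
    with open(manifest, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                index = int(row["index"])
                ml_center = float(row["ml_center_mm"])
                thickness = float(row["thickness_mm"])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{manifest}:{lineno}: bad manifest row") from exc
            if not math.isfinite(ml_center):
                raise ValidationError(
                    f"{manifest}:{lineno}: non-finite ml_center"
                )
            mask_path = root / row["mask_file"]
            if not mask_path.exists():
                raise FormatError(f"missing mask file: {mask_path}")
            mask = _read_mask(mask_path)
            sections.append(
                SectionGeometry(
                    index=index,
                    ml_center=ml_center,
                    thickness=thickness,
                    region_mask=mask,
                )
            )

    somata: list[SomaRecord] = []
    with open(soma_path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                pos = Point3(
                    rc=float(row["rc_mm"]),
                    dv=float(row["dv_mm"]),
                    ml=float(row["ml_mm"]),
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{soma_path}:{lineno}: bad soma row") from exc
            somata.append(
                SomaRecord(
                    soma_id=row["soma_id"], channel=row["channel"], position=pos
                )
            )

    traces: list[FiberTrace] = []
    trace_dir = root / "traces"
    if trace_dir.exists():
        for swc in sorted(trace_dir.glob("*.swc")):
            traces.append(_trace_from_swc(swc.read_text(), str(swc)))

    return Dataset(
        mouse_id=mouse_id,
        sections=sections,
        traces=traces,
        somata=somata,
        provenance=provenance,
    )


def _read_mask(path: Path) -> np.ndarray:
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                rows.append((float(row["rc_mm"]), float(row["dv_mm"])))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad mask vertex") from exc
    return np.array(rows, dtype=float)


def dataset_digest(dataset: Dataset) -> str:
    """Stable content hash of a dataset (used for provenance blocks)."""
    h = hashlib.sha256()
    h.update(dataset.mouse_id.encode())
    for sec in sorted(dataset.sections, key=lambda s: s.index):
        h.update(
            f"{sec.index},{_fmt(sec.ml_center)},{_fmt(sec.thickness)}".encode()
        )
        h.update(np.ascontiguousarray(sec.region_mask).tobytes())
    for t in sorted(dataset.traces, key=lambda t: t.trace_id):
        h.update(f"{t.trace_id},{t.channel},{t.section_index},{t.varicose}".encode())
        h.update(np.ascontiguousarray(t.points).tobytes())
        h.update(np.ascontiguousarray(t.varicosity_positions).tobytes())
    for s in dataset.somata:
        h.update(f"{s.soma_id},{s.channel}".encode())
        h.update(s.position.as_array().tobytes())
    return h.hexdigest()
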
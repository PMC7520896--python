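"""Convergence statistics for dual-channel arborization fits.

Covers the study's quantitative claims about dMSN/iMSN convergence in
the GPe: Euclidean distances between labeled arborization centers
(within-channel G1-G2 / R1-R2 vs cross-channel G1-R1 / G2-R2), the
two-sample Kolmogorov-Smirnov comparison of those distance samples,
binarized box-overlap classification of the projection areas, per-axis
projection-field extents, and co-labeling contingency percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
import shapely
from shapely.geometry import LineString

from .arborfit import ArborizationFit
from .density import DensityGrid
from .trace_io import Dataset, ValidationError

CLASSES = ("gfp_only", "rfp_only", "both")


# ---------------------------------------------------------------------------
# center distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceSet:
    """Within- and cross-channel arborization center distances (mm)."""

    mouse_id: str
    g1_g2: float
    r1_r2: float
    g1_r1: float
    g2_r2: float

    def __post_init__(self) -> None:
        for name in ("g1_g2", "r1_r2", "g1_r1", "g2_r2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def within(self) -> list[float]:
        return [self.g1_g2, self.r1_r2]

    def between(self) -> list[float]:
        return [self.g1_r1, self.g2_r2]


def center_distances(
    fit_gfp: ArborizationFit, fit_rfp: ArborizationFit, mouse_id: str = ""
) -> DistanceSet:
    """Euclidean distances between labeled centers, pairing #1-#1 and #2-#2."""
    for fit in (fit_gfp, fit_rfp):
        if set(fit.components) != {"#1", "#2"}:
            raise ValidationError("fits must carry labels #1 and #2")

    def dist(a, b):
        return float(np.linalg.norm(a - b))

    return DistanceSet(
        mouse_id=mouse_id,
        g1_g2=dist(fit_gfp.mean("#1"), fit_gfp.mean("#2")),
        r1_r2=dist(fit_rfp.mean("#1"), fit_rfp.mean("#2")),
        g1_r1=dist(fit_gfp.mean("#1"), fit_rfp.mean("#1")),
        g2_r2=dist(fit_gfp.mean("#2"), fit_rfp.mean("#2")),
    )


def pool_distances(distance_sets) -> tuple[list[float], list[float]]:
    """Pool within-channel and cross-channel distances across a cohort.

    Each mouse contributes two values to each sample (G1-G2 and R1-R2
    within; G1-R1 and G2-R2 between), so n mice give 2n vs 2n values.
    """
    within, between = [], []
    for ds in distance_sets:
        within.extend(ds.within())
        between.extend(ds.between())
    return within, between


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov comparison
# ---------------------------------------------------------------------------


def ks_compare(
    within_sample, between_sample, method: str = "auto"
) -> tuple[float, float]:
    """Two-sample KS test between pooled distance samples.

    ``method``: "exact" (default for n*m <= 10^4 under "auto"),
    "asymptotic", or "auto".  The study's sample sizes (12 vs 12) sit
    squarely in the exact regime, where the asymptotic p is unreliable.
    Returns (D, p).
    """
    a = np.asarray(list(within_sample), dtype=float)
    b = np.asarray(list(between_sample), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")
    if method == "auto":
        method = "exact" if len(a) * len(b) <= 10_000 else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise ValidationError(f"unknown KS method: {method!r}")
    res = stats.ks_2samp(a, b, method={"exact": "exact", "asymptotic": "asymp"}[method])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# projection-area overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapSummary:
    """Binarized box classification of a mouse's projection areas.

    Boxes containing fiber in exactly one channel are that channel's
    class; boxes with both are "both"; untouched boxes are excluded, so
    percentages are over occupied boxes only.
    """

    mouse_id: str
    box_size: float
    counts: dict  # class -> total box count
    per_section: pd.DataFrame  # section_index, gfp_only, rfp_only, both

    @property
    def total_boxes(self) -> int:
        return sum(self.counts.values())

    def areas_mm2(self) -> dict:
        """Per-class area = box count x box_size^2, in mm^2."""
        a = self.box_size**2
        return {k: v * a for k, v in self.counts.items()}

    def percentages(self) -> dict:
        total = self.total_boxes
        if total == 0:
            return {k: 0.0 for k in CLASSES}
        return {k: 100.0 * v / total for k, v in self.counts.items()}


def classify_boxes(
    grid_gfp: DensityGrid,
    grid_rfp: DensityGrid,
    presence_threshold: float = 0.0,
    mouse_id: str = "",
) -> OverlapSummary:
    """Classify occupied boxes as GFP-only / RFP-only / both.

    A box is "present" for a channel when its fiber length is strictly
    greater than ``presence_threshold`` (default 0 mm).  The two grids
    must share lattice (box size and origin) and section geometry.
    """
    if abs(grid_gfp.box_size - grid_rfp.box_size) > 1e-12:
        raise ValidationError("grids have mismatched box sizes")
    if not np.allclose(grid_gfp.origin, grid_rfp.origin, atol=1e-12):
        raise ValidationError("grids have mismatched lattice origins")
    if grid_gfp.section_ml != grid_rfp.section_ml:
        raise ValidationError("grids have mismatched section sets")

    occ_g = grid_gfp.occupied(presence_threshold)
    occ_r = grid_rfp.occupied(presence_threshold)
    sets = {
        "gfp_only": occ_g - occ_r,
        "rfp_only": occ_r - occ_g,
        "both": occ_g & occ_r,
    }
    counts = {k: len(v) for k, v in sets.items()}
    section_ids = sorted({key[0] for v in sets.values() for key in v})
    rows = []
    for sec in section_ids:
        rows.append(
            {
                "section_index": sec,
                **{k: sum(1 for key in v if key[0] == sec) for k, v in sets.items()},
            }
        )
    per_section = pd.DataFrame(
        rows, columns=["section_index", "gfp_only", "rfp_only", "both"]
    )
    return OverlapSummary(
        mouse_id=mouse_id,
        box_size=grid_gfp.box_size,
        counts=counts,
        per_section=per_section,
    )


def overlap_percentages(cohort_summaries) -> dict:
    """Cohort mean +/- SD (ddof=1) of per-mouse class percentages.

    A single-mouse cohort reports SD 0.0 with ``single_mouse=True``.
    Returns {class: {"mean": .., "sd": ..}, "n_mice": .., "single_mouse": ..}.
    """
    summaries = list(cohort_summaries)
    if not summaries:
        raise ValidationError("need >= 1 mouse summary")
    per_mouse = pd.DataFrame([s.percentages() for s in summaries])
    single = len(summaries) == 1
    out: dict = {"n_mice": len(summaries), "single_mouse": single}
    for cls in CLASSES:
        vals = per_mouse[cls].to_numpy()
        out[cls] = {
            "mean": float(vals.mean()),
            "sd": 0.0 if single else float(vals.std(ddof=1)),
        }
    return out


# ---------------------------------------------------------------------------
# projection extents
# ---------------------------------------------------------------------------


@dataclass
class ExtentSummary:
    """Per-axis range (max - min, mm) of a channel's varicose projection field."""

    channel: str
    rc_range: float
    dv_range: float
    ml_range: float
    empty: bool = False


def projection_extent(dataset: Dataset, channel: str) -> ExtentSummary:
    """Extent of the mask-clipped varicose projection field along each axis.

    rc/dv ranges are over the vertices of varicose polylines after
    clipping to the region masks; the ml range spans the ml centers of
    the sections those clipped fibers touch.  A channel with no varicose
    fiber inside any mask gives an empty-extent summary, not an error.
    """
    rc_vals: list[np.ndarray] = []
    dv_vals: list[np.ndarray] = []
    mls: set[float] = set()
    by_section: dict[int, list] = {}
    for t in dataset.traces_for(channel, varicose_only=True):
        by_section.setdefault(t.section_index, []).append(t.points)
    for sec in dataset.sections:
        pts_list = by_section.get(sec.index)
        if not pts_list:
            continue
        poly = sec.polygon
        touched = False
        for pts in pts_list:
            inter = LineString(pts).intersection(poly)
            if inter.is_empty or inter.length == 0:
                continue
            coords = shapely.get_coordinates(inter)
            if len(coords) == 0:
                continue
            touched = True
            rc_vals.append(coords[:, 0])
            dv_vals.append(coords[:, 1])
        if touched:
            mls.add(sec.ml_center)
    if not rc_vals:
        return ExtentSummary(channel=channel, rc_range=0.0, dv_range=0.0,
                             ml_range=0.0, empty=True)
    rc = np.concatenate(rc_vals)
    dv = np.concatenate(dv_vals)
    return ExtentSummary(
        channel=channel,
        rc_range=float(rc.max() - rc.min()),
        dv_range=float(dv.max() - dv.min()),
        ml_range=float(max(mls) - min(mls)),
    )


# ---------------------------------------------------------------------------
# co-labeling percentages
# ---------------------------------------------------------------------------


def contingency_percentage(positive: int, total: int) -> float:
    """100 * positive / total, rounded half-up to one decimal.

    Reproduces reported marker co-labeling percentages from their counts,
    e.g. 255 of 258 cells -> 98.8.
    """
    if total <= 0:
        raise ValidationError("total must be > 0")
    if not 0 <= positive <= total:
        raise ValidationError("need 0 <= positive <= total")
    pct = Decimal(100 * positive) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
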
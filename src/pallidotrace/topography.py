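"""Soma-distribution summaries and soma-to-arborization topography.

Across a cohort, the per-axis centers of the labeled soma clouds in the
CPu are regressed against the fitted arborization centers in the GPe.
Following the study's plotting convention, the soma (infection) center
is the dependent variable and the arborization center the regressor;
GFP and RFP contribute one point each per mouse, pooled on each panel
by default (6 mice -> 12 points), with per-channel regressions also
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arborfit import LABELS, ArborizationFit
from .trace_io import CHANNELS, Dataset, ValidationError

AXES = ("rc", "dv", "ml")


class DegenerateRegressionError(ValidationError):
    """Regression over constant x has no defined slope."""


@dataclass
class SomaSummary:
    """Per-channel soma cloud summary: count, per-axis center and range (mm)."""

    channel: str
    n_cells: int
    center: np.ndarray  # (rc, dv, ml) mean position
    range: np.ndarray  # per-axis max - min
    empty: bool = False

    def center_axis(self, axis: str) -> float:
        return float(self.center[AXES.index(axis)])


@dataclass
class TopographyResult:
    """One axis-by-arborization regression of soma center on arborization center."""

    axis: str
    label: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_points: int
    channels: str = "pooled"

    @property
    def under_powered(self) -> bool:
        return self.n_points < 3


def soma_summary(dataset: Dataset, channel: str) -> SomaSummary:
    """Unweighted per-axis mean and range of one channel's somata."""
    if channel not in CHANNELS:
        raise ValidationError(f"unknown channel: {channel!r}")
    pos = np.array(
        [s.position.as_array() for s in dataset.somata if s.channel == channel]
    )
    if len(pos) == 0:
        return SomaSummary(
            channel=channel, n_cells=0, center=np.full(3, np.nan),
            range=np.zeros(3), empty=True,
        )
    return SomaSummary(
        channel=channel,
        n_cells=len(pos),
        center=pos.mean(axis=0),
        range=pos.max(axis=0) - pos.min(axis=0),
    )


def axis_regression(x_values, y_values) -> dict:
    """Ordinary least squares y on x with Pearson r and its two-sided p.

    The p-value comes from the t distribution with n - 2 degrees of
    freedom and is NaN for n < 3.  Constant x raises
    :class:`DegenerateRegressionError`.
    """
    x = np.asarray(list(x_values), dtype=float)
    y = np.asarray(list(y_values), dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 2:
        raise ValidationError("need >= 2 points")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # flat response: slope and r are exactly 0, p undefined/1
        return {
            "slope": 0.0,
            "intercept": float(y[0]),
            "pearson_r": 0.0,
            "p_value": float("nan") if len(x) < 3 else 1.0,
            "n_points": len(x),
        }
    res = stats.linregress(x, y)
    p = float(res.pvalue) if len(x) >= 3 else float("nan")
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
        "p_value": p,
        "n_points": len(x),
    }


def topography_report(
    cohort_fits, cohort_soma_summaries, per_channel: bool = True
) -> list[TopographyResult]:
    """Axis-wise regressions of soma centers on arborization centers.

    ``cohort_fits``: per mouse, a mapping channel -> ArborizationFit;
    ``cohort_soma_summaries``: per mouse, a mapping channel ->
    SomaSummary.  For each axis and each arborization label the pooled
    regression uses one point per mouse per channel; with
    ``per_channel=True``, GFP-only and RFP-only regressions are reported
    as well.  Mice missing a channel are skipped for that channel with a
    warning.
    """
    cohort_fits = list(cohort_fits)
    cohort_soma = list(cohort_soma_summaries)
    if len(cohort_fits) != len(cohort_soma):
        raise ValidationError("fits and soma summaries must align per mouse")

    rows: list[TopographyResult] = []
    data: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for i, (fits, somas) in enumerate(zip(cohort_fits, cohort_soma)):
        for ch in CHANNELS:
            fit = fits.get(ch)
            summ = somas.get(ch)
            if fit is None or summ is None or summ.empty:
                warnings.warn(
                    f"mouse {i}: channel {ch} missing a fit or somata; skipped",
                    stacklevel=2,
                )
                continue
            for label in LABELS:
                mean = fit.mean(label)
                for ai, axis in enumerate(AXES):
                    data.setdefault((axis, label, ch), []).append(
                        (float(mean[ai]), summ.center_axis(axis))
                    )

    channel_groups = [("pooled", list(CHANNELS))]
    if per_channel:
        channel_groups += [(ch, [ch]) for ch in CHANNELS]
    for axis in AXES:
        for label in LABELS:
            for group_name, group in channel_groups:
                pts = [p for ch in group for p in data.get((axis, label, ch), [])]
                if len(pts) < 2:
                    continue
                x, y = zip(*pts)
                try:
                    reg = axis_regression(x, y)
                except DegenerateRegressionError:
                    continue
                rows.append(
                    TopographyResult(
                        axis=axis, label=label, channels=group_name, **reg
                    )
                )
    return rows


def topography_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "axis": r.axis,
                "label": r.label,
                "channels": r.channels,
                "slope": r.slope,
                "intercept": r.intercept,
                "pearson_r": r.pearson_r,
                "p_value": r.p_value,
                "n_points": r.n_points,
                "under_powered": r.under_powered,
            }
            for r in results
        ]
    )


def plot_topography(results, cohort_fits, cohort_soma_summaries, path):
    """Scatter panels (axis x arborization) with dotted regression lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    colors = {"GFP": "tab:green", "RFP": "m"}
    fig, ax_grid = plt.subplots(2, 3, figsize=(12, 7))
    pooled = {(r.axis, r.label): r for r in results if r.channels == "pooled"}
    for li, label in enumerate(LABELS):
        for ai, axis in enumerate(AXES):
            ax = ax_grid[li][ai]
            xs_all = []
            for fits, somas in zip(cohort_fits, cohort_soma_summaries):
                for ch in CHANNELS:
                    fit, summ = fits.get(ch), somas.get(ch)
                    if fit is None or summ is None or summ.empty:
                        continue
                    x = float(fit.mean(label)[AXES.index(axis)])
                    xs_all.append(x)
                    ax.scatter(
                        x, summ.center_axis(axis), s=25,
                        color=colors[ch], edgecolors="none",
                    )
            r = pooled.get((axis, label))
            if r is not None and xs_all:
                xs = np.linspace(min(xs_all), max(xs_all), 2)
                ax.plot(xs, r.slope * xs + r.intercept, "k:",
                        label=f"r={r.pearson_r:.2f}")
                ax.legend(fontsize=8)
            ax.set_title(f"Arborization {label}, {axis}")
            ax.set_xlabel(f"arborization center {axis} (mm)")
            ax.set_ylabel(f"soma center {axis} (mm)")
    fig.tight_layout()
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
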
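"""Two-component 3-D Gaussian fit of a channel's fiber-length density.

Each channel's varicose-fiber density is summarized by a mixture of two
3-D Gaussians fitted by weighted expectation-maximization: box centers
from the density grid are the sample points and their fiber lengths the
weights, so the fit maximizes

    L = sum_i w_i log sum_k pi_k N(x_i; mu_k, Sigma_k).

The component with the more rostral (larger rc) mean is labeled "#1" and
the caudal one "#2", following the study's naming of the rostral and
caudal arborizations.  The Mahalanobis-distance-1 ellipsoid of a fitted
component contains chi2(3).cdf(1) ~ 19.9% of the component's mass.

Weighted EM itself is authored here: the M-step multiplies
responsibilities by the point weights, which is what makes a
length-weighted density fit equivalent to fitting every millimeter of
fiber as a separate point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import stats

from .trace_io import ValidationError

LABELS = ("#1", "#2")


class InsufficientDataError(ValidationError):
    """Too few distinct weighted points to fit two components."""


class NumericalError(RuntimeError):
    """The likelihood became non-finite during EM."""


# ---------------------------------------------------------------------------
# components and fits
# ---------------------------------------------------------------------------


@dataclass
class GaussianComponent:
    """One fitted arborization: mean (mm), covariance (mm^2), mixing weight."""

    mean: np.ndarray
    covariance: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(3, 3)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < 1e-6 - 1e-12:
            raise ValidationError(
                "covariance eigenvalues must be >= 1e-6 mm^2 (ridge floor)"
            )
        if not 0.0 < self.weight < 1.0:
            raise ValidationError("mixing weight must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "mean": [float(v) for v in self.mean],
            "covariance": [float(v) for v in self.covariance.ravel()],
            "weight": float(self.weight),
        }


@dataclass
class ArborizationFit:
    """A labeled two-component fit with convergence diagnostics."""

    channel: str
    components: dict  # label -> GaussianComponent
    log_likelihood: float
    n_iterations: int
    converged: bool
    ll_history: list = dc_field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if set(self.components) != set(LABELS):
            raise ValidationError(f"fit must carry labels {LABELS}")
        w = sum(c.weight for c in self.components.values())
        if abs(w - 1.0) > 1e-9:
            raise ValidationError("component weights must sum to 1")
        rc1 = self.components["#1"].mean[0]
        rc2 = self.components["#2"].mean[0]
        if rc1 < rc2 - 1e-9:
            raise ValidationError("label #1 must be the rostral (larger rc) mean")

    def mean(self, label: str) -> np.ndarray:
        return self.components[label].mean

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "components": {k: c.to_dict() for k, c in self.components.items()},
            "log_likelihood": float(self.log_likelihood),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# weighted EM
# ---------------------------------------------------------------------------


def _log_gauss(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = points.shape[1]
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, (points - mean).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * math.log(2.0 * math.pi) + logdet + maha)


def _weighted_moments(points, weights, ridge):
    w = weights / weights.sum()
    mean = w @ points
    diff = points - mean
    cov = (diff * w[:, None]).T @ diff + ridge * np.eye(3)
    return mean, cov


def _init_rc_split(points, weights, jitter_rng=None):
    """Deterministic init: split at the weighted median rc.

    The arborizations are rostrocaudally arranged, so halving the weight
    along rc lands one seed component in each.
    """
    order = np.lexsort((weights, points[:, 2], points[:, 1], points[:, 0]))
    pts, wts = points[order], weights[order]
    cum = np.cumsum(wts)
    split = int(np.searchsorted(cum, 0.5 * cum[-1], side="right"))
    split = min(max(split, 1), len(pts) - 1)
    halves = [(pts[:split], wts[:split]), (pts[split:], wts[split:])]
    params = []
    for hp, hw in halves:
        mean, cov = _weighted_moments(hp, hw, ridge=1e-6)
        params.append((mean, cov, hw.sum() / wts.sum()))
    return params


def _init_random(points, weights, rng):
    p = weights / weights.sum()
    idx = rng.choice(len(points), size=2, replace=False, p=p)
    _, cov = _weighted_moments(points, weights, ridge=1e-6)
    return [(points[i], cov, 0.5) for i in idx]


def _em(points, weights, init_params, tol, max_iter, ridge):
    means = [np.array(m, dtype=float) for m, _, _ in init_params]
    covs = [np.array(c, dtype=float) for _, c, _ in init_params]
    pis = np.array([p for _, _, p in init_params], dtype=float)
    pis /= pis.sum()
    wsum = weights.sum()

    ll_prev = -np.inf
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.column_stack(
            [np.log(pis[k]) + _log_gauss(points, means[k], covs[k]) for k in range(2)]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(weights @ lse)
        if not np.isfinite(ll):
            raise NumericalError(f"non-finite log-likelihood at iteration {n_iter}")
        history.append(ll)
        if ll - ll_prev < tol and n_iter > 1:
            converged = True
            break
        ll_prev = ll

        resp = np.exp(logp - lse[:, None]) * weights[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pis = nk / wsum
        for k in range(2):
            mean = resp[:, k] @ points / nk[k]
            diff = points - mean
            cov = (diff * resp[:, k, None]).T @ diff / nk[k] + ridge * np.eye(3)
            means[k], covs[k] = mean, cov
    return means, covs, pis, history, converged, n_iter


def fit_two_gaussians(
    points: np.ndarray,
    weights: np.ndarray,
    channel: str = "",
    init_strategy: str = "rc_split",
    tol: float = 1e-8,
    max_iter: int = 500,
    ridge: float = 1e-6,
    n_restarts: int = 1,
    seed: int | None = None,
) -> ArborizationFit:
    """Weighted EM fit of exactly two 3-D Gaussians.

    ``points`` is an (n, 3) array (rc, dv, ml) and ``weights`` the
    nonnegative fiber length carried by each point (from
    :func:`~pallidotrace.density.grid_to_weighted_points`).  ``ridge``
    (mm^2) is added to covariance diagonals every M-step; it keeps the ml
    direction well conditioned when fibers occupy few distinct sections.

    The first start is the deterministic rostrocaudal weighted-median
    split; further restarts (``n_restarts`` > 1) draw random pairs of
    points as initial means, and the best final likelihood wins.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValidationError("points must be an (n, 3) array")
    if len(points) != len(weights):
        raise ValidationError("points and weights must have equal length")
    if np.any(weights < 0):
        raise ValidationError("weights must be nonnegative")
    keep = weights > 0
    points, weights = points[keep], weights[keep]
    if len(np.unique(points, axis=0)) < 4 or weights.sum() <= 0:
        raise InsufficientDataError(
            "need >= 4 distinct points with positive total weight"
        )

    rng = np.random.default_rng(seed if seed is not None else 0)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0 and init_strategy == "rc_split":
            init = _init_rc_split(points, weights)
        else:
            init = _init_random(points, weights, rng)
        result = _em(points, weights, init, tol, max_iter, ridge)
        if best is None or result[3][-1] > best[3][-1]:
            best = result
    means, covs, pis, history, converged, n_iter = best

    comps = [
        GaussianComponent(mean=means[k], covariance=covs[k], weight=float(pis[k]))
        for k in range(2)
    ]
    # rostral component is #1; ties on rc broken by dv, then ml, then weight
    def order_key(c: GaussianComponent):
        return (
            round(c.mean[0] / 1e-9),
            round(c.mean[1] / 1e-9),
            round(c.mean[2] / 1e-9),
            c.weight,
        )

    comps.sort(key=order_key, reverse=True)
    return ArborizationFit(
        channel=channel,
        components={"#1": comps[0], "#2": comps[1]},
        log_likelihood=history[-1],
        n_iterations=n_iter,
        converged=converged,
        ll_history=history,
    )


# ---------------------------------------------------------------------------
# Mahalanobis geometry
# ---------------------------------------------------------------------------


@dataclass
class SectionEllipse:
    """Intersection of a Mahalanobis ellipsoid with a section plane ml=c."""

    center: np.ndarray  # (rc, dv)
    axes: np.ndarray  # columns = principal directions in-plane
    semi_axes: np.ndarray  # lengths (mm)


@dataclass
class Ellipsoid:
    """The region of Mahalanobis distance <= radius around a component mean."""

    center: np.ndarray
    axes: np.ndarray  # columns = eigenvectors of the covariance
    semi_axes: np.ndarray  # radius * sqrt(eigenvalues)
    radius: float
    covariance: np.ndarray

    def mahalanobis(self, x) -> float:
        d = np.asarray(x, dtype=float) - self.center
        return float(math.sqrt(d @ np.linalg.solve(self.covariance, d)))

    def contains(self, x) -> bool:
        return self.mahalanobis(x) <= self.radius

    def section_ellipse(self, ml: float) -> SectionEllipse | None:
        """In-plane ellipse at the plane ml = const, or None if disjoint."""
        if self.radius == 0:
            return None
        prec = np.linalg.inv(self.covariance)
        A = prec[:2, :2]
        b = prec[:2, 2]
        d = prec[2, 2]
        z = ml - self.center[2]
        y0 = -z * np.linalg.solve(A, b)
        r2 = self.radius**2 - z**2 * (d - b @ np.linalg.solve(A, b))
        if r2 <= 0:
            return None
        evals, evecs = np.linalg.eigh(A)
        return SectionEllipse(
            center=self.center[:2] + y0,
            axes=evecs,
            semi_axes=np.sqrt(r2 / evals),
        )


def mahalanobis_region(component: GaussianComponent, radius: float = 1.0) -> Ellipsoid:
    """Ellipsoid {x : (x-mu)^T Sigma^-1 (x-mu) <= radius^2}.

    Principal axes are the covariance eigenvectors; semi-axis lengths are
    radius * sqrt(eigenvalues).  radius=0 degenerates to the mean point.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    evals, evecs = np.linalg.eigh(component.covariance)
    if evals.min() <= 0:
        raise NumericalError("singular covariance")
    return Ellipsoid(
        center=component.mean.copy(),
        axes=evecs,
        semi_axes=radius * np.sqrt(evals),
        radius=float(radius),
        covariance=component.covariance.copy(),
    )


def mass_within(radius: float, dim: int = 3) -> float:
    """Gaussian probability mass inside Mahalanobis distance ``radius``.

    Equals the chi-square CDF with ``dim`` degrees of freedom at
    radius^2; for radius 1 in 3-D this is ~0.199 — the "approximately
    20%" of the mass enclosed by the unit-Mahalanobis ellipsoid.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    return float(stats.chi2.cdf(radius**2, df=dim))
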
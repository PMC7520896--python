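"""Synthetic mice with known ground truth.

The generator emulates the structure of the study's traced data: a
compact cloud of labeled somata in the dorsal striatum (CPu), and for
each fluorescence channel a field of varicose axon fibers in a
GPe-shaped region whose length density follows a two-component 3-D
Gaussian mixture.  The direct-pathway (GFP) field is narrower and
sparser than, and nested inside, the indirect-pathway (RFP) field; the
two channels share (up to configuration) the same component centers;
and across a cohort the arborization centers follow a configurable
linear topographic map of the injection (soma) centroid.

Fibers are realized as stationary first-order autoregressive
(Ornstein-Uhlenbeck-like) random walks in the section plane: each fiber
draws a mixture component, fixes its mediolateral position from the
component's ml marginal (selecting its section), and walks in (rc, dv)
with the component's in-plane Gaussian as the walk's exact stationary
law.  Vertex occupancy therefore matches the configured mixture while
the data remain per-section 2-D polylines, as in the study's tracing.
Varicosities are dropped along each fiber at exponential (memoryless)
arc-length spacings.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .trace_io import (
    CHANNELS,
    Dataset,
    FiberTrace,
    Point3,
    SectionGeometry,
    SomaRecord,
    ValidationError,
)

AXES = ("rc", "dv", "ml")
LABELS = ("#1", "#2")


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible child stream of a master seed.

    One shared stream per mouse is split into named substreams (somata,
    fibers, varicosities) so regenerating one part never perturbs another.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    ints += [zlib.crc32(str(k).encode()) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass(frozen=True)
class ContingencyTable:
    """Co-labeling counts for one marker pair (e.g. Cre+ cells also PPD+)."""

    positive: int
    total: int
    marker_pair: str = ""

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError("contingency total must be > 0")
        if not 0 <= self.positive <= self.total:
            raise ValidationError("need 0 <= positive <= total")


@dataclass
class SynthConfig:
    """Full parameterization of a synthetic mouse.

    Defaults emulate the study's reported conditions: ~0.5 (rc) x 0.8 (dv)
    x 0.5 (ml) mm soma clouds of ~29 GFP+ and ~23 RFP+ cells in the CPu;
    two arborizations near rc -0.35 and -0.55 mm in a GPe-like region; an
    RFP field with 1.5x the GFP covariance and more fibers; and identity
    dorsoventral/mediolateral topography with no rostrocaudal dependence.
    All lengths in mm.
    """

    # injection site (soma cloud)
    soma_center: tuple[float, float, float] = (0.5, -2.8, 2.0)
    soma_spread: tuple[float, float, float] = (0.13, 0.20, 0.13)
    n_somata: dict = field(default_factory=lambda: {"GFP": 29, "RFP": 23})

    # topography: per-axis (slope, intercept), soma centroid -> arborization
    # mid-center.  Defaults: no rc dependence, identity-like dv and ml maps.
    topo_map: dict = field(
        default_factory=lambda: {
            "rc": (0.0, -0.45),
            "dv": (1.0, -0.5),
            "ml": (1.0, -0.1),
        }
    )

    # arborization mixture: rostral (#1) / caudal (#2) component offsets
    # from the mid-center, shared per-axis SDs, per-channel covariance scale
    arborization_offsets: dict = field(
        default_factory=lambda: {
            "#1": (0.10, 0.10, 0.0),
            "#2": (-0.10, -0.10, 0.0),
        }
    )
    arbor_sd: tuple[float, float, float] = (0.06, 0.09, 0.09)
    channel_scales: dict = field(default_factory=lambda: {"GFP": 1.0, "RFP": 1.5})
    mixture_weights: dict = field(
        default_factory=lambda: {"GFP": (0.5, 0.5), "RFP": (0.5, 0.5)}
    )

    # fiber statistics
    n_fibers: dict = field(default_factory=lambda: {"GFP": 150, "RFP": 350})
    fiber_step: float = 0.01
    fiber_len_mean: float = 1.5
    varicosity_spacing: float = 0.01
    gfp_nonvaricose_fraction: float = 0.1  # some GFP fibers lack boutons

    # sectioning
    section_span: tuple[float, float] = (1.4, 2.4)
    thickness: float = 0.02

    # GPe-like region mask: ellipse around the arborization mid-center
    mask_semiaxes: tuple[float, float] = (0.60, 0.80)
    mask_vertices: int = 48

    seed: int = 0

    def __post_init__(self) -> None:
        for name, vals in (
            ("soma_spread", self.soma_spread),
            ("arbor_sd", self.arbor_sd),
        ):
            if any(v <= 0 for v in vals):
                raise ValidationError(f"{name} entries must be > 0")
        for name, v in (
            ("fiber_step", self.fiber_step),
            ("fiber_len_mean", self.fiber_len_mean),
            ("varicosity_spacing", self.varicosity_spacing),
            ("thickness", self.thickness),
        ):
            if v <= 0:
                raise ValidationError(f"{name} must be > 0")
        for ch in CHANNELS:
            w = np.asarray(self.mixture_weights[ch], dtype=float)
            if len(w) != 2 or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"mixture_weights[{ch}] must be two positive values summing to 1"
                )
            if self.channel_scales[ch] <= 0:
                raise ValidationError(f"channel_scales[{ch}] must be > 0")
        if self.channel_scales["RFP"] < self.channel_scales["GFP"]:
            warnings.warn(
                "channel_scales[RFP] < channel_scales[GFP]: the iMSN field is "
                "narrower than the dMSN field, unlike the emulated geometry",
                stacklevel=2,
            )
        if self.section_span[1] <= self.section_span[0]:
            raise ValidationError("section_span must be increasing")

    # -- derived ground truth -------------------------------------------

    def arbor_mid_center(self, soma_center=None) -> np.ndarray:
        """Topographic image of the soma centroid (mid-point of #1 and #2)."""
        c = np.asarray(soma_center if soma_center is not None else self.soma_center)
        return np.array(
            [self.topo_map[ax][0] * c[i] + self.topo_map[ax][1]
             for i, ax in enumerate(AXES)]
        )

    def component_means(self, soma_center=None) -> dict:
        mid = self.arbor_mid_center(soma_center)
        return {
            lab: mid + np.asarray(self.arborization_offsets[lab], dtype=float)
            for lab in LABELS
        }

    def component_cov(self, channel: str) -> np.ndarray:
        scale = float(self.channel_scales[channel])
        return np.diag(np.asarray(self.arbor_sd, dtype=float) ** 2) * scale

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("soma_center", "soma_spread", "arbor_sd", "section_span",
                    "mask_semiaxes"):
            if key in d:
                d[key] = tuple(d[key])
        if "topo_map" in d:
            d["topo_map"] = {k: tuple(v) for k, v in d["topo_map"].items()}
        if "arborization_offsets" in d:
            d["arborization_offsets"] = {
                k: tuple(v) for k, v in d["arborization_offsets"].items()
            }
        if "mixture_weights" in d:
            d["mixture_weights"] = {
                k: tuple(v) for k, v in d["mixture_weights"].items()
            }
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _region_mask(config: SynthConfig, soma_center=None) -> np.ndarray:
    """GPe-outline stand-in: an ellipse around the arborization field."""
    mid = config.arbor_mid_center(soma_center)
    a, b = config.mask_semiaxes
    th = np.linspace(0.0, 2.0 * np.pi, config.mask_vertices, endpoint=False)
    return np.column_stack([mid[0] + a * np.cos(th), mid[1] + b * np.sin(th)])


def _build_sections(config: SynthConfig, soma_center=None) -> list[SectionGeometry]:
    lo, hi = config.section_span
    n = max(1, int(round((hi - lo) / config.thickness)))
    mask = _region_mask(config, soma_center)
    return [
        SectionGeometry(
            index=i,
            ml_center=lo + (i + 0.5) * config.thickness,
            thickness=config.thickness,
            region_mask=mask,
        )
        for i in range(n)
    ]


def _ou_walk(rng: np.random.Generator, n: int, mean2: np.ndarray,
             sd2: np.ndarray, rho: float) -> np.ndarray:
    """Stationary AR(1) walk: every vertex is marginally N(mean2, diag(sd2^2))."""
    eps = rng.standard_normal((n, 2)) * (sd2 * math.sqrt(1.0 - rho * rho))
    eps[0] = rng.standard_normal(2) * sd2  # stationary start
    out = np.empty((n, 2))
    acc = eps[0]
    out[0] = acc
    for t in range(1, n):  # short fibers; plain loop is fast enough
        acc = rho * acc + eps[t]
        out[t] = acc
    return out + mean2


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def small_config(**overrides) -> SynthConfig:
    """A reduced-size configuration for replicate-heavy simulation studies.

    Same geometry, topography, and channel asymmetry as the defaults but
    fewer, shorter fibers and thicker sections, so hundreds of mice can
    be generated and analyzed in seconds.  Keyword overrides are applied
    on top.
    """
    params = dict(
        n_fibers={"GFP": 60, "RFP": 120},
        fiber_len_mean=0.8,
        thickness=0.04,
        section_span=(1.5, 2.3),
    )
    params.update(overrides)
    return SynthConfig(**params)


def generate_dataset(
    config: SynthConfig,
    seed: int | None = None,
    mouse_id: str = "synth",
) -> Dataset:
    """Generate one synthetic mouse.

    Deterministic: identical (config, seed) pairs produce identical
    datasets.  ``seed`` defaults to ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    soma_center = np.asarray(config.soma_center, dtype=float)
    sections = _build_sections(config, soma_center)
    lo, hi = config.section_span
    means = config.component_means(soma_center)

    # somata -----------------------------------------------------------
    rng_s = substream(seed, "somata")
    somata: list[SomaRecord] = []
    spread = np.asarray(config.soma_spread)
    for ch in CHANNELS:
        n = int(config.n_somata[ch])
        pos = soma_center + rng_s.standard_normal((n, 3)) * spread
        for j in range(n):
            somata.append(
                SomaRecord(
                    soma_id=f"{ch}-soma-{j:03d}",
                    channel=ch,
                    position=Point3(*pos[j]),
                )
            )

    # fibers -----------------------------------------------------------
    traces: list[FiberTrace] = []
    for ch in CHANNELS:
        rng_f = substream(seed, "fibers", ch)
        rng_v = substream(seed, "varicosities", ch)
        weights = np.asarray(config.mixture_weights[ch], dtype=float)
        cov = config.component_cov(ch)
        sd = np.sqrt(np.diag(cov))
        sd2, sd_ml = sd[:2], sd[2]
        # AR(1) coefficient chosen so the mean step is ~ fiber_step
        sbar = float(np.sqrt(np.mean(sd2**2)))
        rho = math.sqrt(max(0.0, 1.0 - (config.fiber_step / sbar) ** 2))
        n_fibers = int(config.n_fibers[ch])
        nonvar = (
            config.gfp_nonvaricose_fraction if ch == "GFP" else 0.0
        )
        for i in range(n_fibers):
            k = int(rng_f.random() < weights[1])  # 0 -> #1, 1 -> #2
            mean = means[LABELS[k]]
            # fix the fiber's ml from the component marginal; rejection
            # keeps it inside the sectioned span
            for _ in range(200):
                ml = mean[2] + sd_ml * rng_f.standard_normal()
                if lo < ml < hi:
                    break
            else:
                ml = min(max(mean[2], lo + 1e-6), hi - 1e-6)
            sec = int((ml - lo) / config.thickness)
            sec = min(max(sec, 0), len(sections) - 1)

            n_steps = max(
                2,
                1 + int(round(rng_f.exponential(config.fiber_len_mean)
                              / config.fiber_step)),
            )
            pts = _ou_walk(rng_f, n_steps, mean[:2], sd2, rho)
            varicose = not (ch == "GFP" and rng_f.random() < nonvar)
            length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            if varicose and length > 0:
                gaps = rng_v.exponential(
                    config.varicosity_spacing,
                    size=max(4, int(3 * length / config.varicosity_spacing)),
                )
                pos = np.cumsum(gaps)
                vpos = pos[pos <= length]
            else:
                vpos = np.empty(0)
            traces.append(
                FiberTrace(
                    trace_id=f"{ch}-fiber-{i:04d}",
                    channel=ch,
                    section_index=sec,
                    points=pts,
                    varicose=varicose,
                    varicosity_positions=vpos,
                )
            )

    return Dataset(
        mouse_id=mouse_id,
        sections=sections,
        traces=traces,
        somata=somata,
        provenance=f"synthgen:{config.digest()}:seed={seed}",
    )


def generate_cohort(
    config: SynthConfig,
    n_mice: int,
    injection_jitter: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int | None = None,
) -> list[Dataset]:
    """Generate a cohort with jittered injection sites.

    Mouse ``i``'s soma center is the configured center plus a seeded
    Gaussian displacement with per-axis SD ``injection_jitter``; its
    arborization centers follow the configured topographic map applied to
    the displaced center, so the cohort embeds a known linear topography.
    """
    if n_mice < 1:
        raise ValidationError("n_mice must be >= 1")
    if seed is None:
        seed = config.seed
    jitter = np.asarray(injection_jitter, dtype=float)
    if n_mice == 1 and np.all(jitter == 0):
        # degenerate cohort: exactly the single-mouse generator output
        return [generate_dataset(config, seed=seed, mouse_id="mouse01")]
    rng = substream(seed, "cohort")
    out = []
    for i in range(n_mice):
        shift = rng.standard_normal(3) * jitter
        center = np.asarray(config.soma_center) + shift
        child_seed = int(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        cfg_i = replace(config, soma_center=tuple(center))
        out.append(
            generate_dataset(cfg_i, seed=child_seed, mouse_id=f"mouse{i + 1:02d}")
        )
    return out


def generate_colabel_counts(
    p_true: float, n_cells: int, seed: int = 0, marker_pair: str = ""
) -> ContingencyTable:
    """Binomial co-labeling counts (synthetic analogue of marker-overlap tallies)."""
    if not 0.0 <= p_true <= 1.0:
        raise ValidationError("p_true must lie in [0, 1]")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = substream(seed, "colabel", marker_pair)
    return ContingencyTable(
        positive=int(rng.binomial(n_cells, p_true)),
        total=int(n_cells),
        marker_pair=marker_pair,
    )
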
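"""Shared fixtures: tiny hand-built datasets and one cached synthetic mouse."""

from __future__ import annotations

import numpy as np
import pytest

from pallidotrace import (
    Dataset,
    FiberTrace,
    Point3,
    SectionGeometry,
    SomaRecord,
    SynthConfig,
    generate_dataset,
)

SQUARE = np.array([[-2.0, -6.0], [2.0, -6.0], [2.0, 0.0], [-2.0, 0.0]])


def square_section(index: int = 0, ml: float = 1.9,
                   mask: np.ndarray = SQUARE) -> SectionGeometry:
    return SectionGeometry(index=index, ml_center=ml, region_mask=mask)


def one_trace_dataset(points, channel="GFP", varicose=True, varic=(),
                      mask=SQUARE) -> Dataset:
    return Dataset(
        mouse_id="tiny",
        sections=[square_section(mask=mask)],
        traces=[
            FiberTrace(
                trace_id="t0", channel=channel, section_index=0,
                points=np.asarray(points), varicose=varicose,
                varicosity_positions=np.asarray(varic, dtype=float),
            )
        ],
        somata=[
            SomaRecord("s0", "GFP", Point3(0.5, -2.8, 2.0)),
            SomaRecord("s1", "RFP", Point3(0.45, -2.7, 2.1)),
        ],
    )


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def default_mouse(default_config) -> Dataset:
    """One synthetic mouse at default (paper-emulating) problem size."""
    return generate_dataset(default_config, seed=11)


@pytest.fixture(scope="session")
def small_mouse():
    """A fast, reduced-size mouse for I/O and plumbing tests."""
    from pallidotrace.synthgen import small_config

    return generate_dataset(small_config(), seed=7)
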
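"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from statomorph import (
    PipelineConfig,
    default_templates,
    extract_dataset,
    generate_dataset,
    run_face_combination_cda,
)
from statomorph.io import FACES
from statomorph.outlines import Outline

#: Seed of the standard full-size synthetic study used by the heavy
#: end-to-end tests; every test that needs the default data set shares it.
FULL_DATASET_SEED = 7


# --------------------------------------------------------------------------
# Shape builders
# --------------------------------------------------------------------------

def make_circle(r: float = 1.0, n: int = 360, center=(0.0, 0.0)) -> Outline:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(
        points=np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    )


def make_ellipse(a: float = 2.0, b: float = 1.0, n: int = 3600) -> Outline:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(points=np.column_stack([a * np.cos(t), b * np.sin(t)]))


def make_square(side: float = 1.0) -> Outline:
    s = side
    return Outline(points=np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float))


def make_blob(seed: int, n_harmonics: int = 8, n_points: int = 700) -> Outline:
    """Irregular but simple closed curve from random low-amplitude harmonics."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = 3.0 * np.cos(t) + 1.2 * np.sin(t)
    y = 2.0 * np.sin(t)
    for n in range(2, n_harmonics + 1):
        amp = 0.35 / n**2
        x = x + rng.normal(0, amp) * np.cos(n * t) + rng.normal(0, amp) * np.sin(n * t)
        y = y + rng.normal(0, amp) * np.cos(n * t) + rng.normal(0, amp) * np.sin(n * t)
    return Outline(points=np.column_stack([x, y]))


# --------------------------------------------------------------------------
# Independent elliptical Fourier oracle: dense numerical integration
# --------------------------------------------------------------------------

def fourier_integration_oracle(outline: Outline, n_harmonics: int, subdiv: int = 400):
    """Fourier coefficients of the arc-length parameterized polygon by
    dense midpoint-rule integration (independent of the chain-sum path).

    Each polygon edge is split into ``subdiv`` equal pieces; x(t), y(t) are
    evaluated at piece midpoints and the Fourier integrals
    (2/T) * integral f(t) cos(2 pi n t / T) dt are summed numerically.
    """
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    T = seglen.sum()
    frac = (np.arange(subdiv) + 0.5) / subdiv
    # midpoints of every sub-segment, with their parameter value and weight
    t0 = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    tm = (t0[:, None] + frac[None, :] * seglen[:, None]).ravel()
    w = np.repeat(seglen / subdiv, subdiv)
    xm = (closed[:-1, 0][:, None] + frac[None, :] * seg[:, 0][:, None]).ravel()
    ym = (closed[:-1, 1][:, None] + frac[None, :] * seg[:, 1][:, None]).ravel()

    out = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        c = np.cos(2 * np.pi * n * tm / T)
        s = np.sin(2 * np.pi * n * tm / T)
        out[n - 1] = [
            2 / T * np.sum(xm * c * w),
            2 / T * np.sum(xm * s * w),
            2 / T * np.sum(ym * c * w),
            2 / T * np.sum(ym * s * w),
        ]
    dc = (np.sum(xm * w) / T, np.sum(ym * w) / T)
    return out, dc


# --------------------------------------------------------------------------
# Data-set fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory):
    """Small rendered study: first 3 species, n = 5, 192 px images."""
    out = tmp_path_factory.mktemp("smoke")
    templates = default_templates()[:3]
    for t in templates:
        t.n_default = 5
    return generate_dataset(templates, seed=21, out_dir=out, image_px=192)


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    """The complete default study: 12 species, 185 specimens, 555 images,
    extracted once and analysed at both grouping levels."""
    out = tmp_path_factory.mktemp("full")
    templates = default_templates()
    ds = generate_dataset(templates, seed=FULL_DATASET_SEED, out_dir=out)
    config = PipelineConfig(out_dir=str(out / "results"))
    data = extract_dataset(ds.manifest_path, config)
    species = run_face_combination_cda(
        data.features, data.labels, face_set=FACES, level="species"
    )
    family = run_face_combination_cda(
        data.features, data.labels, face_set=FACES, level="family"
    )
    return {
        "dataset": ds,
        "config": config,
        "data": data,
        "species": species,
        "family": family,
    }
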
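"""Elliptical Fourier analysis of closed outlines.

A closed outline parameterized by arc length t in [0, T) decomposes into

    x(t) = A0 + sum_n [ A_n cos(2*pi*n*t/T) + B_n sin(2*pi*n*t/T) ]
    y(t) = C0 + sum_n [ C_n cos(2*pi*n*t/T) + D_n sin(2*pi*n*t/T) ]

Each harmonic n contributes an ellipse; the quadruple (A_n, B_n, C_n, D_n)
is the harmonic's coefficient set.  Coefficients are computed with the
exact piecewise-linear (chain-sum) formulas of Kuhl & Giardina over the
polygon, which makes them independent of how densely the polygon is
sampled — no FFT, no resampling step.

Normalization to the first harmonic removes size, rotation and trace
starting point (and nothing else — reflection is a real shape difference
and is kept).  After normalization A1 = 1, B1 = C1 = 0 and D1 carries the
aspect of the best-fitting ellipse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AssemblyError,
    DegenerateShapeError,
    NormalizationError,
    ParameterError,
)
from .io import FACES, SampleMeta
from .outlines import Outline

_FACE_ABBREV = {"proximal": "prox", "oral": "oral", "lateral": "lat"}


@dataclass
class EFACoeffs:
    """Elliptical Fourier coefficients for one outline.

    ``harmonics`` is an (H, 4) array with columns (A_n, B_n, C_n, D_n) for
    n = 1..H.  ``dc`` holds the centroid terms (A0, C0).  Raw coefficients
    are in micrometres; normalized coefficients are dimensionless with
    harmonic 1 fixed at (1, 0, 0, D1).
    """

    harmonics: np.ndarray
    dc: tuple[float, float]
    normalized: bool
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=np.float64)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ParameterError(f"harmonics must be (H, 4) with H >= 1, got {h.shape}")
        self.harmonics = h

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]


@dataclass
class HarmonicPower:
    """Per-harmonic power (A²+B²+C²+D²)/2 and its cumulative fraction."""

    per_harmonic: np.ndarray
    cumulative_fraction: np.ndarray


def efa_decompose(outline: Outline, n_harmonics: int = 20) -> EFACoeffs:
    """Raw elliptical Fourier coefficients of a closed polygonal outline.

    Uses the chain-sum formulas: with segment vectors (dx_i, dy_i), chord
    lengths dt_i and cumulative arc length t_i,

        A_n = T / (2 n² π²) * sum_i (dx_i/dt_i)(cos φ_i - cos φ_{i-1}),

    φ_i = 2πn t_i / T, and analogously for B (sin, dx), C (cos, dy),
    D (sin, dy).  These are the exact Fourier integrals of the
    piecewise-linear curve, so the coefficients of a polygon are computed
    without discretization error.
    """
    if n_harmonics < 1:
        raise ParameterError("n_harmonics must be >= 1")
    pts = outline.points
    d = np.roll(pts, -1, axis=0) - pts
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    T = float(dt.sum())
    if T == 0.0 or d.shape[0] < 2:
        raise DegenerateShapeError("outline has zero total perimeter")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    t1, t2 = t[:-1], t[1:]

    n = np.arange(1, n_harmonics + 1, dtype=np.float64)[:, None]
    w = 2.0 * np.pi * n / T
    dcos = np.cos(w * t2) - np.cos(w * t1)
    dsin = np.sin(w * t2) - np.sin(w * t1)
    scale = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    A = scale * (vx * dcos).sum(axis=1)
    B = scale * (vx * dsin).sum(axis=1)
    C = scale * (vy * dcos).sum(axis=1)
    D = scale * (vy * dsin).sum(axis=1)

    # DC terms: arc-length average of the piecewise-linear coordinates;
    # each segment contributes its midpoint weighted by its length.
    mids = pts[keep] + 0.5 * d
    a0 = float((mids[:, 0] * dt).sum() / T)
    c0 = float((mids[:, 1] * dt).sum() / T)

    return EFACoeffs(
        harmonics=np.column_stack([A, B, C, D]),
        dc=(a0, c0),
        normalized=False,
        meta=outline.meta,
    )


def _rot(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def _apply_normalization(h: np.ndarray, theta: float) -> tuple[np.ndarray, float]:
    """Shift start point by theta, rotate the major axis to x, unit-scale."""
    H = h.shape[0]
    out = np.empty_like(h)
    n_arr = np.arange(1, H + 1)
    for i, n in enumerate(n_arr):
        G = h[i].reshape(2, 2)
        out[i] = (G @ _rot(n * theta)).ravel()
    a1, b1, c1, d1 = out[0]
    E = float(np.hypot(a1, c1))
    if E <= 0:
        raise NormalizationError("degenerate first-harmonic ellipse")
    psi = float(np.arctan2(c1, a1))
    R = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for i in range(H):
        out[i] = (R @ out[i].reshape(2, 2)).ravel()
    return out / E, E


def canonicalize_even_sign(h: np.ndarray) -> np.ndarray:
    """Resolve the half-period starting-point ambiguity.

    First-harmonic normalization leaves one discrete ambiguity: shifting
    the start point by half the outline period (and re-orienting) negates
    every even harmonic while leaving odd harmonics unchanged.  The
    convention here: the largest-magnitude coefficient among the even
    harmonics is made positive.
    """
    even = h[1::2]
    if even.size == 0:
        return h
    flat = even.ravel()
    lead = flat[int(np.argmax(np.abs(flat)))]
    if lead < 0:
        out = h.copy()
        out[1::2] *= -1.0
        return out
    return h


def efa_normalize(coeffs: EFACoeffs) -> EFACoeffs:
    """Normalize coefficients to the first harmonic.

    The starting point is rotated onto the first-harmonic ellipse's major
    axis, the shape is rotated so that axis is horizontal, and all
    coefficients are divided by the semi-major axis length.  The result is
    invariant to similarity transforms (uniform scale, rotation,
    translation) and to the starting index of the trace; reflection is not
    removed.
    """
    if coeffs.normalized:
        return coeffs
    a1, b1, c1, d1 = coeffs.harmonics[0]
    if np.hypot(a1, c1) == 0 and np.hypot(b1, d1) == 0:
        raise NormalizationError("first harmonic is zero")
    theta0 = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    # The stationary angles of the first-harmonic radius are theta0 + k*pi/2;
    # pick one where the x-aligned semi-axis is the major one, then fix the
    # remaining half-period ambiguity by the even-harmonic sign convention.
    for k in range(4):
        theta = theta0 + k * np.pi / 2.0
        G = coeffs.harmonics[0].reshape(2, 2) @ _rot(theta)
        if np.hypot(G[0, 0], G[1, 0]) >= np.hypot(G[0, 1], G[1, 1]):
            break
    h, _ = _apply_normalization(coeffs.harmonics, float(theta))
    h = canonicalize_even_sign(h)
    # clamp the analytically-zero entries
    h[0, 0] = 1.0
    h[0, 1] = 0.0
    h[0, 2] = 0.0
    return EFACoeffs(harmonics=h, dc=(0.0, 0.0), normalized=True, meta=coeffs.meta)


def harmonic_power(coeffs: EFACoeffs) -> HarmonicPower:
    """Power spectrum of the coefficients.

    power_n = (A_n² + B_n² + C_n² + D_n²)/2 — half the squared Frobenius
    norm of the harmonic, proportional to the area-scale of the n-th
    ellipse.  Cumulative fractions are relative to the total over the
    computed harmonics.
    """
    p = 0.5 * (coeffs.harmonics**2).sum(axis=1)
    total = p.sum()
    cum = np.cumsum(p) / total if total > 0 else np.zeros_like(p)
    return HarmonicPower(per_harmonic=p, cumulative_fraction=cum)


def min_harmonics_for_power(coeffs: EFACoeffs, threshold: float) -> int:
    """Smallest n whose cumulative power fraction reaches ``threshold``.

    If the threshold is not reached within the computed harmonics (possible
    only through floating-point shortfall), the harmonic count is returned
    with a warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must be in (0, 1)")
    cum = harmonic_power(coeffs).cumulative_fraction
    idx = np.searchsorted(cum, threshold)
    if idx >= len(cum):
        warnings.warn(
            f"power threshold {threshold} unreachable with "
            f"{coeffs.n_harmonics} harmonics",
            stacklevel=2,
        )
        return coeffs.n_harmonics
    return int(idx) + 1


def efa_reconstruct(
    coeffs: EFACoeffs, n_harmonics: int | None = None, n_points: int = 360
) -> Outline:
    """Inverse Fourier synthesis of the outline at ``n_points`` samples."""
    H = coeffs.n_harmonics
    if n_harmonics is None:
        n_harmonics = H
    if n_harmonics > H:
        raise ParameterError(f"n_harmonics {n_harmonics} exceeds computed H={H}")
    if n_harmonics < 1:
        raise ParameterError("n_harmonics must be >= 1")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, n_harmonics + 1)[:, None]
    cos = np.cos(n * t)
    sin = np.sin(n * t)
    h = coeffs.harmonics[:n_harmonics]
    x = coeffs.dc[0] + h[:, 0] @ cos + h[:, 1] @ sin
    y = coeffs.dc[1] + h[:, 2] @ cos + h[:, 3] @ sin
    return Outline(points=np.column_stack([x, y]), meta=coeffs.meta)


def feature_columns(
    face_set: Sequence[str], harmonic_range: tuple[int, int] = (2, 20)
) -> list[str]:
    """Deterministic column order of the feature matrix.

    Faces in canonical order (proximal, oral, lateral); within a face,
    harmonics ascending; within a harmonic, coefficients A, B, C, D.
    """
    lo, hi = harmonic_range
    cols = []
    for face in FACES:
        if face not in face_set:
            continue
        ab = _FACE_ABBREV[face]
        for n in range(lo, hi + 1):
            for letter in "ABCD":
                cols.append(f"{letter}{n}_{ab}")
    return cols


def build_feature_matrix(
    samples: Iterable[EFACoeffs],
    face_set: Sequence[str],
    harmonic_range: tuple[int, int] = (2, 20),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-specimen feature vectors of normalized coefficients.

    Harmonic 1 is never included: after normalization A1, B1, C1 are
    constants, and D1 depends on how the silhouette was oriented, so the
    informative shape variables are the quadruples for harmonics in
    ``harmonic_range`` — 76 per face for the default range 2-20.

    Returns
    -------
    (features, labels)
        ``features``: one row per specimen, indexed by specimen_id, columns
        from :func:`feature_columns`.  ``labels``: species and family per
        specimen, same index.
    """
    face_set = list(face_set)
    if not face_set:
        raise ParameterError("face_set must not be empty")
    unknown = [f for f in face_set if f not in FACES]
    if unknown:
        raise ParameterError(f"unknown faces {unknown}")
    lo, hi = harmonic_range
    if lo < 2 or hi < lo:
        raise ParameterError(f"invalid harmonic_range {harmonic_range}")

    by_specimen: dict[str, dict[str, EFACoeffs]] = {}
    info: dict[str, tuple[str, str]] = {}
    for c in samples:
        if not c.normalized:
            raise AssemblyError(
                f"coefficients for {c.meta and c.meta.specimen_id} are not normalized"
            )
        if c.n_harmonics < hi:
            raise AssemblyError(
                f"specimen {c.meta.specimen_id}: {c.n_harmonics} harmonics "
                f"computed, need >= {hi}"
            )
        m = c.meta
        by_specimen.setdefault(m.specimen_id, {})[m.face] = c
        info[m.specimen_id] = (m.species, m.family)

    missing = {
        sid: [f for f in face_set if f not in faces]
        for sid, faces in by_specimen.items()
        if any(f not in faces for f in face_set)
    }
    if missing:
        raise AssemblyError(f"specimens missing required faces: {missing}")

    cols = feature_columns(face_set, harmonic_range)
    sids = sorted(by_specimen)
    rows = np.empty((len(sids), len(cols)))
    for r, sid in enumerate(sids):
        parts = []
        for face in FACES:
            if face not in face_set:
                continue
            h = by_specimen[sid][face].harmonics[lo - 1 : hi]
            parts.append(h.ravel())
        rows[r] = np.concatenate(parts)
    features = pd.DataFrame(rows, index=pd.Index(sids, name="specimen_id"), columns=cols)
    labels = pd.DataFrame(
        {"species": [info[s][0] for s in sids], "family": [info[s][1] for s in sids]},
        index=features.index,
    )
    return features, labels
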
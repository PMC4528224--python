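"""Shared fixtures: analytic shapes, independent oracles, small run configs."""

from __future__ import annotations

import numpy as np
import pytest

from wingid.config import RunConfig
from wingid.efd import EFDSet, reconstruct
from wingid.synthetic import ShapeFamilySpec, shipped_prototypes


def circle_points(r=5.0, k=2000, phase=0.0, centre=(0.0, 0.0)):
    """Closed circle sampled at uniform speed, (t, x, y) rows."""
    theta = phase + np.linspace(0, 2 * np.pi, k + 1)
    x = centre[0] + r * np.cos(theta)
    y = centre[1] + r * np.sin(theta)
    t = np.linspace(0, 2 * np.pi * r, k + 1)
    return np.column_stack([t, x, y])


def quadrature_efd(points, n_harmonics, grid_points=200_001):
    """Independent dense-quadrature oracle for the Fourier integrals.

    Linearly interpolates x(t), y(t) on a dense grid (original vertices
    included so the piecewise-linear curve is represented exactly) and
    integrates x cos, x sin, y cos, y sin with the trapezoid rule.
    """
    from wingid.efd import _as_closed_txy

    t, x, y = _as_closed_txy(points)
    T = t[-1] - t[0]
    tt = t - t[0]
    grid = np.unique(np.concatenate([np.linspace(0.0, T, grid_points), tt]))
    xg = np.interp(grid, tt, x)
    yg = np.interp(grid, tt, y)
    rows = []
    for n in range(1, n_harmonics + 1):
        c = np.cos(2 * np.pi * n * grid / T)
        s = np.sin(2 * np.pi * n * grid / T)
        rows.append([
            2 / T * np.trapezoid(xg * c, grid),
            2 / T * np.trapezoid(xg * s, grid),
            2 / T * np.trapezoid(yg * c, grid),
            2 / T * np.trapezoid(yg * s, grid),
        ])
    return np.array(rows)


@pytest.fixture(scope="session")
def wing_coeffs():
    """Band-limited asymmetric wing-like prototype coefficients."""
    spec = ShapeFamilySpec("falcate", shipped_prototypes()["falcate"])
    return spec.coefficient_matrix()


@pytest.fixture(scope="session")
def wing_points(wing_coeffs):
    """Dense polygon sampling of the wing prototype (x, y only)."""
    return reconstruct(EFDSet(coeffs=wing_coeffs), wing_coeffs.shape[0], n_points=800)


@pytest.fixture(scope="session")
def fast_config():
    """Small-but-real GA/CV settings for unit tests of the classifier."""
    return RunConfig(n_harmonics=15, n_runs=2, cv_folds=3,
                     ga_population=8, ga_generations=5)


def disk_image(radius=40, size=128, fg=0, bg=255, centre=None):
    """uint8 image with a filled disk."""
    if centre is None:
        centre = (size // 2, size // 2)
    rr, cc = np.mgrid[0:size, 0:size]
    mask = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2
    img = np.full((size, size), bg, dtype=np.uint8)
    img[mask] = fg
    return img, mask
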
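"""Elliptic Fourier descriptors (EFD) of closed outlines.

A closed outline parameterized by arc length ``t`` over one period ``T`` is
expanded harmonic by harmonic as

.. math::

    x(t) = A_0 + \\sum_{n\\ge 1} a_n \\cos\\frac{2n\\pi t}{T}
                 + b_n \\sin\\frac{2n\\pi t}{T}, \\qquad
    y(t) = C_0 + \\sum_{n\\ge 1} c_n \\cos\\frac{2n\\pi t}{T}
                 + d_n \\sin\\frac{2n\\pi t}{T}.

Because a chain-coded outline is piecewise linear, the Fourier integrals have
an exact closed form over each segment (Kuhl & Giardina's formulation); this
module evaluates those exact sums rather than an FFT over resampled points,
so the coefficients inherit no resampling error.

The descriptor set supports:

* Kuhl–Giardina normalization removing size, rotation, translation and the
  arbitrary trace starting point (after which ``a_1 = 1, b_1 = 0, c_1 = 0``);
* rotation-invariant per-harmonic magnitudes (CE) whose cumulative variation
  indicates how many harmonics carry real shape information;
* truncated-series outline reconstruction and the mean pointwise
  reconstruction error ``epsilon_n``;
* flattening to the ``4N - 3`` feature vector consumed by the classifier
  (117 features at the default 30 harmonics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateOutlineError, WingidError

__all__ = [
    "EFDSet",
    "HarmonicDiagnostics",
    "FeatureVector",
    "compute_efd",
    "normalize",
    "compute_ce",
    "reconstruct",
    "evaluate_series",
    "reconstruction_error",
    "to_feature_vector",
    "from_feature_vector",
    "feature_names",
    "write_feature_table",
    "read_feature_table",
]


@dataclass(frozen=True)
class EFDSet:
    """Elliptic Fourier coefficients of one outline.

    Attributes
    ----------
    coeffs : ndarray, shape (N, 4)
        Rows ``(a_n, b_n, c_n, d_n)`` for harmonics ``n = 1..N``.  Pixel
        units before normalization, dimensionless after.
    dc : tuple of float
        The DC terms ``(A_0, C_0)`` (outline centroid); dropped (set to 0)
        by normalization, which makes the descriptor translation invariant.
    total_T : float
        Perimeter length (the parameter period).
    normalized : bool
        Whether Kuhl–Giardina normalization has been applied.
    """

    coeffs: np.ndarray
    dc: tuple = (0.0, 0.0)
    total_T: float = 1.0
    normalized: bool = False

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise WingidError("coeffs must be an (N, 4) array with N >= 1")
        if not np.all(np.isfinite(c)):
            raise WingidError("non-finite elliptic Fourier coefficients")
        object.__setattr__(self, "coeffs", c)

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class HarmonicDiagnostics:
    """Per-harmonic diagnostics used to choose the harmonic content number.

    ``ce`` is a rotation-invariant magnitude per harmonic; ``ce_variation[i]``
    is the first difference of the cumulative CE between harmonics ``i+1``
    and ``i+2`` (length ``N - 1``) — the quantity that flattens to ~0 once
    extra harmonics stop adding shape information.  ``epsilon`` holds the
    reconstruction error per harmonic count when computed, and ``K`` the
    number of original outline points it was measured over.
    """

    ce: np.ndarray
    ce_variation: np.ndarray
    epsilon: np.ndarray | None = None
    K: int | None = None


@dataclass(frozen=True)
class FeatureVector:
    """Flattened normalized coefficients minus the three constants.

    Ordering is the a-block, b-block, c-block, d-block with the constants
    ``a_1 = 1, b_1 = 0, c_1 = 0`` removed:
    ``(a_2..a_N, b_2..b_N, c_2..c_N, d_1..d_N)``, length ``4N - 3``.
    """

    values: np.ndarray
    label: str | None = None
    source: str | None = None

    @property
    def n_harmonics(self) -> int:
        return (len(self.values) + 3) // 4


# ---------------------------------------------------------------------------
# coefficient computation
# ---------------------------------------------------------------------------

def _as_closed_txy(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (t, x, y) grids of a closed polyline, last vertex == first.

    Accepts either an ``(K, 3)`` array of ``(t, x, y)`` rows (e.g. from
    :func:`wingid.chaincode.to_coordinates`) or an ``(K, 2)`` array of
    ``(x, y)`` vertices.  For (t, x, y) input the endpoint must return to the
    start within tolerance, otherwise the curve is open and rejected.  For
    plain vertices the closing segment back to the first vertex is implicit
    and ``t`` is the cumulative chord length.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise WingidError("points must be (K, 2) of (x, y) or (K, 3) of (t, x, y)")
    if pts.shape[1] == 3:
        t, x, y = pts[:, 0], pts[:, 1], pts[:, 2]
        scale = max(np.ptp(x), np.ptp(y), 1.0)
        if np.hypot(x[-1] - x[0], y[-1] - y[0]) > 1e-6 * scale:
            raise WingidError("open curve: endpoint does not return to the start")
        if np.any(np.diff(t) <= 0):
            raise WingidError("arc-length parameter t must be strictly increasing")
        return t, x, y
    xy = pts
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 3:
        raise WingidError("need at least 3 distinct vertices")
    closed = np.vstack([xy, xy[:1]])
    seg = np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1]))
    if np.any(seg == 0):
        keep = np.concatenate([[True], seg[:-1] > 0])
        xy = xy[keep]
        closed = np.vstack([xy, xy[:1]])
        seg = np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1]))
    t = np.concatenate([[0.0], np.cumsum(seg)])
    return t, closed[:, 0], closed[:, 1]


def compute_efd(points, n_harmonics: int) -> EFDSet:
    """Exact piecewise-linear elliptic Fourier transform of a closed outline.

    Parameters
    ----------
    points : array-like
        ``(K, 3)`` rows of ``(t, x, y)`` (chain-code output) or ``(K, 2)``
        vertices of a closed polygon (closing edge implicit).
    n_harmonics : int
        Number of harmonics N >= 1 to compute.

    Returns
    -------
    EFDSet
        Unnormalized coefficients in the input's length units, with DC terms
        set to the outline centroid and ``total_T`` the perimeter.

    Notes
    -----
    Over segment ``i`` the curve is linear in ``t``, so each harmonic's
    integral reduces to the classical closed form

    ``a_n = T / (2 n^2 pi^2) * sum_i (dx_i / dt_i)
    [cos(2 n pi t_i / T) - cos(2 n pi t_{i-1} / T)]``

    (and analogously with sin for ``b_n`` and with ``dy`` for ``c_n, d_n``),
    which this function evaluates vectorized over all harmonics and segments.
    """
    if n_harmonics < 1:
        raise WingidError("n_harmonics must be >= 1")
    t, x, y = _as_closed_txy(points)
    if len(t) < 8:
        raise WingidError(f"closed outline needs >= 8 points, got {len(t)}")
    T = t[-1] - t[0]
    tt = t - t[0]
    dx, dy, dt = np.diff(x), np.diff(y), np.diff(tt)

    n = np.arange(1, n_harmonics + 1, dtype=float)[:, None]
    ang = 2.0 * np.pi * n * tt[None, :] / T
    dcos = np.diff(np.cos(ang), axis=1)
    dsin = np.diff(np.sin(ang), axis=1)
    pref = T / (2.0 * (n * np.pi) ** 2)
    vx = dx / dt
    vy = dy / dt
    a = (pref * (vx[None, :] * dcos)).sum(axis=1)
    b = (pref * (vx[None, :] * dsin)).sum(axis=1)
    c = (pref * (vy[None, :] * dcos)).sum(axis=1)
    d = (pref * (vy[None, :] * dsin)).sum(axis=1)

    # DC terms: mean of the piecewise-linear x(t), y(t) over one period.
    xi = np.concatenate([[0.0], np.cumsum(dx)[:-1]])
    zeta = np.concatenate([[0.0], np.cumsum(dy)[:-1]])
    A0 = x[0] + (np.sum(xi * dt) + 0.5 * np.sum(dx * dt)) / T
    C0 = y[0] + (np.sum(zeta * dt) + 0.5 * np.sum(dy * dt)) / T

    return EFDSet(
        coeffs=np.column_stack([a, b, c, d]),
        dc=(float(A0), float(C0)),
        total_T=float(T),
        normalized=False,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _phase_rotate(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the trace starting point: harmonic n right-multiplied by R(n*theta)."""
    n = np.arange(1, coeffs.shape[0] + 1, dtype=float)
    cn, sn = np.cos(n * theta), np.sin(n * theta)
    a, b, c, d = coeffs.T
    return np.column_stack([
        a * cn + b * sn, -a * sn + b * cn,
        c * cn + d * sn, -c * sn + d * cn,
    ])


def _spatial_rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the curve by -psi in the plane: left-multiply every harmonic."""
    cp, sp = np.cos(psi), np.sin(psi)
    a, b, c, d = coeffs.T
    return np.column_stack([
        cp * a + sp * c, cp * b + sp * d,
        -sp * a + cp * c, -sp * b + cp * d,
    ])


def normalize(efd: EFDSet) -> EFDSet:
    """Kuhl–Giardina size / rotation / starting-point normalization.

    Three steps: (i) rotate the parameter origin to where the first-harmonic
    ellipse crosses its semi-major axis (starting-point invariance), (ii)
    rotate the plane by the semi-major axis angle (orientation invariance),
    (iii) divide by the semi-major magnitude (size invariance).  The DC terms
    are dropped, giving translation invariance.  Afterwards the first
    harmonic is exactly ``(1, 0, 0, d_1)``; reflection is deliberately NOT
    removed, so mirror-imaged outlines keep distinct descriptors.

    The semi-major crossing leaves a residual two-fold ambiguity (either end
    of the axis).  It is resolved deterministically: the variant is chosen in
    which the first even-harmonic coefficient of appreciable magnitude is
    positive, so identical shapes traced from different starting pixels map
    to bitwise-comparable descriptors.

    Raises
    ------
    DegenerateOutlineError
        If the first-harmonic magnitude is below 1e-12 (degenerate outline).
    """
    if efd.normalized:
        return efd
    a1, b1, c1, d1 = efd.coeffs[0]
    if a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1 < 1e-24:
        raise DegenerateOutlineError("degenerate outline: first-harmonic magnitude ~ 0")

    theta0 = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    # theta0 lands on an extremum of the first-ellipse radius; pick the
    # candidate (theta0 or theta0 + pi/2) on the major axis.
    best = None
    for k in (0, 1):
        th = theta0 + k * np.pi / 2.0
        cc = _phase_rotate(efd.coeffs, th)
        mag = cc[0, 0] ** 2 + cc[0, 2] ** 2
        if best is None or mag > best[0] + 1e-15 * (1 + best[0]):
            best = (mag, cc)
    coeffs = best[1]

    psi = np.arctan2(coeffs[0, 2], coeffs[0, 0])
    coeffs = _spatial_rotate(coeffs, psi)
    scale = coeffs[0, 0]  # == sqrt(a1'^2 + c1'^2) >= 0 by construction
    if scale < 1e-12:
        raise DegenerateOutlineError("degenerate outline: first-harmonic magnitude ~ 0")
    coeffs = coeffs / scale

    coeffs = _canonical_axis_end(coeffs)
    # numerical exactness of the three constants
    coeffs[0, 0], coeffs[0, 1], coeffs[0, 2] = 1.0, 0.0, 0.0
    return EFDSet(coeffs=coeffs, dc=(0.0, 0.0), total_T=efd.total_T, normalized=True)


def _canonical_axis_end(coeffs: np.ndarray) -> np.ndarray:
    """Resolve the 180-degree major-axis ambiguity.

    Starting the parameter at the opposite end of the semi-major axis negates
    every even harmonic while leaving odd harmonics (including the first)
    unchanged.  Scan even harmonics in (a, b, c, d) order and flip if the
    first coefficient exceeding a relative threshold is negative.
    """
    if coeffs.shape[0] < 2:
        return coeffs
    tol = 1e-7 * max(1.0, np.abs(coeffs).max())
    even = coeffs[1::2]  # harmonics 2, 4, ...
    flat = even.ravel()
    idx = np.flatnonzero(np.abs(flat) > tol)
    if len(idx) and flat[idx[0]] < 0:
        out = coeffs.copy()
        out[1::2] *= -1.0
        return out
    return coeffs


# ---------------------------------------------------------------------------
# diagnostics, reconstruction, features
# ---------------------------------------------------------------------------

def compute_ce(efd: EFDSet, formula: str = "granlund") -> HarmonicDiagnostics:
    """Rotation-invariant per-harmonic magnitudes and their cumulative variation.

    ``formula='granlund'`` (default) uses
    ``CE_i = sqrt((a_i^2 + c_i^2)/2) + sqrt((b_i^2 + d_i^2)/2)``;
    ``formula='power'`` uses the harmonic power
    ``(a_i^2 + b_i^2 + c_i^2 + d_i^2)/2``.  Both are invariant to rotations
    of the input outline, and both flatten once harmonics stop contributing.
    """
    if efd.n_harmonics < 2:
        raise WingidError("CE diagnostics need at least 2 harmonics")
    a, b, c, d = efd.coeffs.T
    if formula == "granlund":
        ce = np.sqrt((a**2 + c**2) / 2.0) + np.sqrt((b**2 + d**2) / 2.0)
    elif formula == "power":
        ce = (a**2 + b**2 + c**2 + d**2) / 2.0
    else:
        raise WingidError(f"unknown CE formula {formula!r}")
    cum = np.cumsum(ce)
    return HarmonicDiagnostics(ce=ce, ce_variation=np.abs(np.diff(cum)))


def evaluate_series(efd: EFDSet, n_use: int, t) -> np.ndarray:
    """Evaluate the truncated series at parameter values ``t`` (in [0, T])."""
    if n_use < 1:
        raise WingidError("n_use must be >= 1")
    if n_use > efd.n_harmonics:
        raise WingidError(f"n_use={n_use} exceeds available harmonics ({efd.n_harmonics})")
    t = np.asarray(t, dtype=float)
    n = np.arange(1, n_use + 1, dtype=float)[:, None]
    ang = 2.0 * np.pi * n * t[None, :] / efd.total_T
    cosang, sinang = np.cos(ang), np.sin(ang)
    a, b, c, d = efd.coeffs[:n_use].T
    x = efd.dc[0] + (a[:, None] * cosang + b[:, None] * sinang).sum(axis=0)
    y = efd.dc[1] + (c[:, None] * cosang + d[:, None] * sinang).sum(axis=0)
    return np.column_stack([x, y])


def reconstruct(efd: EFDSet, n_use: int, n_points: int = 256) -> np.ndarray:
    """Rebuild the outline from the first ``n_use`` harmonics.

    Returns ``(n_points, 2)`` coordinates at parameter values uniformly
    spaced over one period (endpoint excluded; the curve is closed).
    """
    if n_points < 3:
        raise WingidError("n_points must be >= 3")
    t = np.linspace(0.0, efd.total_T, n_points, endpoint=False)
    return evaluate_series(efd, n_use, t)


def reconstruction_error(original, efd: EFDSet, n_use: int) -> float:
    """Mean pointwise distance epsilon_n between outline and reconstruction.

    The truncated series is evaluated at the SAME arc-length parameters
    ``t_k`` as the original points, and
    ``epsilon_n = (1/K) * sum_k || (x_k, y_k) - (x_nk, y_nk) ||``.
    """
    t, x, y = _as_closed_txy(original)
    rec = evaluate_series(efd, n_use, t - t[0])
    return float(np.mean(np.hypot(x - rec[:, 0], y - rec[:, 1])))


def feature_names(n_harmonics: int) -> list[str]:
    """Column names of the flattened feature vector, e.g. a2..aN, b2.., c2.., d1..dN."""
    return (
        [f"a{i}" for i in range(2, n_harmonics + 1)]
        + [f"b{i}" for i in range(2, n_harmonics + 1)]
        + [f"c{i}" for i in range(2, n_harmonics + 1)]
        + [f"d{i}" for i in range(1, n_harmonics + 1)]
    )


def to_feature_vector(efd: EFDSet, label: str | None = None, source: str | None = None) -> FeatureVector:
    """Flatten a normalized EFDSet, dropping the constants a_1, b_1, c_1."""
    if not efd.normalized:
        raise WingidError("feature vectors require a normalized EFDSet")
    a, b, c, d = efd.coeffs.T
    values = np.concatenate([a[1:], b[1:], c[1:], d])
    return FeatureVector(values=values, label=label, source=source)


def from_feature_vector(fv: FeatureVector, total_T: float = 1.0) -> EFDSet:
    """Re-inflate a feature vector into the normalized EFDSet it came from."""
    if (len(fv.values) + 3) % 4 != 0:
        raise WingidError("feature vector length must be 4N - 3")
    n = fv.n_harmonics
    v = np.asarray(fv.values, dtype=float)
    a = np.concatenate([[1.0], v[: n - 1]])
    b = np.concatenate([[0.0], v[n - 1 : 2 * (n - 1)]])
    c = np.concatenate([[0.0], v[2 * (n - 1) : 3 * (n - 1)]])
    d = v[3 * (n - 1) :]
    return EFDSet(coeffs=np.column_stack([a, b, c, d]), dc=(0.0, 0.0), total_T=total_T, normalized=True)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table (source, label, feature columns) as CSV."""
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)
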
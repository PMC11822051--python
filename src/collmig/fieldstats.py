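"""Collectivity statistics over velocity fields.

The central readout is the spatial velocity autocorrelation

    C(r) = < dv_i . dv_j >_{|x_i - x_j| ~ r} / < |dv|^2 >,

where dv are the per-frame mean-subtracted velocity vectors; C(0) = 1 by
normalization. The correlation length is the first 1/e crossing of C(r)
(linear interpolation between bracketing bins), with a least-squares
exponential fit available as a cross-check. This mean-subtracted vector
dot-product definition is one of several in use for monolayer migration and
is documented as this package's choice; the component-wise variant gives
the same C(r) because the components enter the dot product additively.

Pair sums are accumulated over frames (pooling by evidence, not averaging
per-frame profiles) and invalid or interpolated PIV vectors are excluded.
On a rectangular grid the exact all-pairs sums are computed via FFT
autocorrelation of the masked component images, which is O(N log N).

Angle convention for rose histograms: image coordinates (y down); 0 deg is
the inward wound normal and +90 deg points along +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .piv import VelocityField
from .tracking import Track

__all__ = [
    "CorrelationProfile",
    "CorrelationLengthResult",
    "OrientationHistogram",
    "DegenerateFluctuationError",
    "velocity_autocorrelation",
    "correlation_length",
    "orientation_histogram",
    "order_parameter",
    "velocity_field_from_tracks",
]


class DegenerateFluctuationError(ValueError):
    """Raised when a field has zero velocity fluctuation after mean
    subtraction ('degenerate: zero fluctuation')."""


@dataclass
class CorrelationProfile:
    """Radially binned velocity autocorrelation.

    lag_bins are bin-center lags in um (lag 0 is its own bin, so C[0] = 1
    exactly); n_pairs counts vector pairs per bin; bins with zero pairs are
    omitted.
    """

    lag_bins: np.ndarray
    C: np.ndarray
    n_pairs: np.ndarray
    bin_width: float
    correlation_length: float | None = None
    method_tag: str | None = None


@dataclass(frozen=True)
class CorrelationLengthResult:
    value_um: float
    method: str
    censored: bool = False


@dataclass
class OrientationHistogram:
    """Fractional rose histogram of vector angles relative to the inward
    wound normal, on (-180, 180]."""

    bin_edges: np.ndarray
    fraction: np.ndarray
    n_vectors: int
    reference_direction: tuple[float, float]


def _field_fluctuations(field: VelocityField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = field.measurable & np.isfinite(field.u) & np.isfinite(field.v)
    if not mask.any():
        return np.zeros_like(field.u), np.zeros_like(field.v), mask
    du = np.where(mask, field.u - field.u[mask].mean(), 0.0)
    dv = np.where(mask, field.v - field.v[mask].mean(), 0.0)
    return du, dv, mask


def _grid_spacing(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 1.0
    d = np.diff(coords)
    if not np.allclose(d, d[0]):
        raise ValueError("velocity field grid must be uniformly spaced")
    return float(d[0])


def velocity_autocorrelation(
    fields: list[VelocityField] | VelocityField,
    bin_width: float,
    max_lag: float,
) -> CorrelationProfile:
    """Radially binned, frame-pooled spatial velocity autocorrelation.

    Per frame the field-mean velocity is subtracted; pair dot products and
    pair counts are accumulated into radial bins of width ``bin_width`` um
    up to ``max_lag``; C is normalized so that the zero-lag bin equals 1.
    Raises :class:`DegenerateFluctuationError` if the pooled fluctuation is
    zero (e.g. a spatially uniform field) and ``ValueError`` if no field has
    a valid vector.
    """
    if isinstance(fields, VelocityField):
        fields = [fields]
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_edges = int(np.ceil(max_lag / bin_width)) + 1  # bin 0 = zero lag only
    num = np.zeros(n_edges)
    cnt = np.zeros(n_edges)
    sq_speed_sum = 0.0
    n_vectors = 0
    any_valid = False
    for field in fields:
        du, dv, mask = _field_fluctuations(field)
        if not mask.any():
            continue
        any_valid = True
        sq_speed_sum += float((field.u[mask] ** 2 + field.v[mask] ** 2).sum())
        n_vectors += int(mask.sum())
        sx = _grid_spacing(field.grid_x)
        sy = _grid_spacing(field.grid_y)
        ny, nx = du.shape
        fy, fx = 2 * ny, 2 * nx
        fm = np.fft.rfft2(mask.astype(float), s=(fy, fx))
        pair_cnt = np.fft.irfft2(fm * np.conj(fm), s=(fy, fx))
        acc = np.zeros((fy, fx))
        for comp in (du, dv):
            fc = np.fft.rfft2(comp, s=(fy, fx))
            acc += np.fft.irfft2(fc * np.conj(fc), s=(fy, fx))
        lag_y = np.fft.fftfreq(fy, 1.0 / fy).astype(int)
        lag_x = np.fft.fftfreq(fx, 1.0 / fx).astype(int)
        r = np.hypot(np.abs(lag_y)[:, None] * sy, np.abs(lag_x)[None, :] * sx)
        idx = np.where(r == 0.0, 0, np.ceil(r / bin_width).astype(int))
        keep = (r <= max_lag) & (np.abs(lag_y)[:, None] < ny) & (np.abs(lag_x)[None, :] < nx)
        np.add.at(num, idx[keep], acc[keep])
        np.add.at(cnt, idx[keep], np.round(pair_cnt[keep]))
    if not any_valid:
        raise ValueError("no field contains a valid vector")
    # fluctuation energy negligible relative to the raw velocity magnitude
    # (covers both exactly uniform fields and float-rounding residue)
    mean_sq_speed = sq_speed_sum / max(n_vectors, 1)
    if num[0] <= 1e-12 * mean_sq_speed * cnt[0] or num[0] == 0.0:
        raise DegenerateFluctuationError("degenerate: zero fluctuation")
    norm = num[0] / cnt[0]  # pooled <|dv|^2>
    nonzero = cnt > 0
    centers = np.concatenate([[0.0], (np.arange(1, n_edges) - 0.5) * bin_width])
    C = (num[nonzero] / cnt[nonzero]) / norm
    return CorrelationProfile(
        lag_bins=centers[nonzero],
        C=C,
        n_pairs=cnt[nonzero].astype(int),
        bin_width=bin_width,
    )


def correlation_length(
    profile: CorrelationProfile, method: str = "one_over_e"
) -> CorrelationLengthResult:
    """Correlation length in um from a binned profile.

    ``one_over_e`` (default): smallest lag where C first crosses 1/e, by
    linear interpolation between the bracketing bins. If C never drops below
    1/e within the profile the maximum lag is returned flagged censored.
    ``exp_fit``: least-squares fit of exp(-r/lambda) over bins with C > 0.05.
    """
    if len(profile.lag_bins) < 3:
        raise ValueError("profile needs at least 3 bins")
    r, C = profile.lag_bins, profile.C
    if method == "one_over_e":
        target = 1.0 / np.e
        below = np.nonzero(C < target)[0]
        if len(below) == 0:
            return CorrelationLengthResult(float(r[-1]), method, censored=True)
        i = below[0]
        if i == 0:  # pragma: no cover - C[0] is 1 by normalization
            return CorrelationLengthResult(float(r[0]), method)
        t = (C[i - 1] - target) / (C[i - 1] - C[i])
        return CorrelationLengthResult(float(r[i - 1] + t * (r[i] - r[i - 1])), method)
    if method == "exp_fit":
        sel = C > 0.05
        if sel.sum() < 2:
            raise ValueError("too few bins with C > 0.05 for exponential fit")
        guess = correlation_length(profile, "one_over_e").value_um
        popt, _ = curve_fit(lambda x, lam: np.exp(-x / lam), r[sel], C[sel],
                            p0=[max(guess, profile.bin_width)])
        return CorrelationLengthResult(float(popt[0]), method)
    raise ValueError(f"unknown method {method!r}")


def _relative_angles_deg(u: np.ndarray, v: np.ndarray, normal: tuple[float, float]) -> np.ndarray:
    """Signed angle of (u, v) vs the inward normal, image coords (y down)."""
    nx, ny = normal
    dot = u * nx + v * ny
    cross = nx * v - ny * u  # z of n x d with y down => +90 for +y against +x
    ang = np.degrees(np.arctan2(cross, dot))
    ang[ang <= -180.0] += 360.0
    return ang


def orientation_histogram(
    fields: list[VelocityField] | VelocityField,
    wound_normal: tuple[float, float] = (1.0, 0.0),
    n_bins: int = 36,
) -> OrientationHistogram:
    """Rose histogram of valid vector orientations relative to the inward
    wound normal; zero-magnitude vectors are skipped."""
    if isinstance(fields, VelocityField):
        fields = [fields]
    angles = []
    for f in fields:
        m = f.measurable & (np.hypot(f.u, f.v) > 0)
        if m.any():
            angles.append(_relative_angles_deg(f.u[m], f.v[m], wound_normal))
    if not angles:
        raise ValueError("no valid nonzero vector")
    angles = np.concatenate(angles)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # half-open (lo, hi] bins so that an angle on an edge (e.g. +90) falls in
    # the bin below it, matching the (-180, 180] angle range
    idx = np.clip(np.searchsorted(edges, angles, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return OrientationHistogram(
        bin_edges=edges,
        fraction=counts / counts.sum(),
        n_vectors=int(counts.sum()),
        reference_direction=wound_normal,
    )


def order_parameter(field: VelocityField) -> float:
    """Magnitude of the mean unit velocity vector, in [0, 1]."""
    mag = np.hypot(field.u, field.v)
    m = field.measurable & (mag > 0)
    if not m.any():
        raise ValueError("order parameter undefined: no valid nonzero vector")
    ux = field.u[m] / mag[m]
    uy = field.v[m] / mag[m]
    return float(np.hypot(ux.mean(), uy.mean()))


def velocity_field_from_tracks(
    tracks: list[Track],
    frame: int,
    grid_spacing_um: float,
    box: tuple[float, float],
    frame_index: int | None = None,
) -> VelocityField:
    """Grid per-cell velocities (step from ``frame`` to ``frame + 1``) into a
    rectangular VelocityField, averaging cells per grid cell.

    Provides the bridge from ground-truth simulator trajectories to the
    field statistics without the imaging/PIV stage.
    """
    w, h = box
    nx = max(int(np.floor(w / grid_spacing_um)), 1)
    ny = max(int(np.floor(h / grid_spacing_um)), 1)
    u_sum = np.zeros((ny, nx))
    v_sum = np.zeros((ny, nx))
    n = np.zeros((ny, nx))
    for tr in tracks:
        pos = np.nonzero(tr.frames == frame)[0]
        nxt = np.nonzero(tr.frames == frame + 1)[0]
        if len(pos) == 0 or len(nxt) == 0:
            continue
        i0, i1 = pos[0], nxt[0]
        dt_h = (tr.t_min[i1] - tr.t_min[i0]) / 60.0
        gx = min(int(tr.x_um[i0] / grid_spacing_um), nx - 1)
        gy = min(int(tr.y_um[i0] / grid_spacing_um), ny - 1)
        u_sum[gy, gx] += (tr.x_um[i1] - tr.x_um[i0]) / dt_h
        v_sum[gy, gx] += (tr.y_um[i1] - tr.y_um[i0]) / dt_h
        n[gy, gx] += 1
    valid = n > 0
    with np.errstate(invalid="ignore"):
        u = np.where(valid, u_sum / np.maximum(n, 1), 0.0)
        v = np.where(valid, v_sum / np.maximum(n, 1), 0.0)
    centers_x = (np.arange(nx) + 0.5) * grid_spacing_um
    centers_y = (np.arange(ny) + 0.5) * grid_spacing_um
    return VelocityField(grid_x=centers_x, grid_y=centers_y, u=u, v=v, valid=valid,
                         frame_index=frame if frame_index is None else frame_index)
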
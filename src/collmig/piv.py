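"""Particle image velocimetry by windowed zero-normalized cross-correlation.

Each interrogation window of frame A is correlated (FFT, zero-padded, mean
subtracted) against the co-located window of frame B; the correlation peak
gives the integer displacement and a three-point Gaussian fit refines it to
sub-pixel precision, falling back to a parabolic fit when a neighbouring
correlation value is non-positive. Vectors from flat (zero-variance)
windows are flagged invalid rather than propagated as NaN, and a
normalized-median test replaces spurious vectors by their neighbourhood
median.

Coordinates: origin top-left, x rightward, y downward, 0-based pixel
indices; window centers sit at ``offset + window/2`` pixels. Public outputs
are in um and um/h.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PIVConfig",
    "VelocityField",
    "compute_piv_pair",
    "validate_field",
    "piv_movie",
    "um_per_h_to_nm_per_s",
    "nm_per_s_to_um_per_h",
]

_FLAT_EPS = 1e-12


def um_per_h_to_nm_per_s(v: np.ndarray | float) -> np.ndarray | float:
    return v * (1000.0 / 3600.0)


def nm_per_s_to_um_per_h(v: np.ndarray | float) -> np.ndarray | float:
    return v * 3.6


@dataclass(frozen=True)
class PIVConfig:
    """PIV parameters.

    window_size: interrogation window edge in px (even, >= 8).
    overlap_fraction: fraction of window shared by neighbours, in [0, 1).
    subpixel_method: 'gaussian3pt' (default) or 'parabolic'.
    outlier_threshold: normalized-median test residual threshold.
    pixel_size: um per px. frame_interval: minutes between frames.
    """

    window_size: int = 32
    overlap_fraction: float = 0.5
    subpixel_method: str = "gaussian3pt"
    outlier_threshold: float = 2.0
    pixel_size: float = 1.0
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        if self.window_size < 8 or self.window_size % 2:
            raise ValueError("window_size must be even and >= 8")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subpixel_method not in ("gaussian3pt", "parabolic"):
            raise ValueError(f"unknown subpixel_method {self.subpixel_method!r}")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")


@dataclass
class VelocityField:
    """Gridded velocity field in physical units.

    grid_x / grid_y are the window-center coordinates in um (1D, uniformly
    spaced); u / v are velocity components in um/h on the (y, x) grid with
    y pointing down; ``valid`` flags measured vectors and ``interpolated``
    flags vectors replaced during validation.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray | None = None
    frame_index: int = 0
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.valid, dtype=bool)

    @property
    def measurable(self) -> np.ndarray:
        """Vectors usable for statistics: valid and not interpolated."""
        return self.valid & ~self.interpolated


def _subpixel_offset(cm: float, c0: float, cp: float, method: str) -> float:
    """One-axis sub-pixel peak offset from three correlation samples."""
    if method == "gaussian3pt" and cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = 2.0 * (lm + lp - 2.0 * l0)
        if denom < 0:
            return float((lm - lp) / denom)
    denom = 2.0 * (cm + cp - 2.0 * c0)
    if denom < 0:
        return float((cm - cp) / denom)
    return 0.0


def _window_displacement(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, float, bool]:
    """Displacement (dx, dy) of window content b relative to a, px."""
    if a.size == 0 or b.size == 0 or a.shape != b.shape:
        return 0.0, 0.0, False
    a = a - a.mean()
    b = b - b.mean()
    if a.std() < _FLAT_EPS or b.std() < _FLAT_EPS:
        return 0.0, 0.0, False
    w = a.shape[0]
    size = 2 * w
    fa = np.fft.rfft2(a, s=(size, size))
    fb = np.fft.rfft2(b, s=(size, size))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(size, size))
    lags = np.fft.fftfreq(size, d=1.0 / size).astype(int)  # 0..w-1, -w..-1
    # restrict the search to displacements within half a window
    half = w // 2
    ok = np.abs(lags) <= half
    sub = corr[np.ix_(ok, ok)]
    sub_lags = lags[ok]
    peak = sub.max()
    ties = np.argwhere(sub >= peak - 1e-12 * max(abs(peak), 1.0))
    # deterministic tie-break: smallest displacement magnitude first
    mags = [sub_lags[i] ** 2 + sub_lags[j] ** 2 for i, j in ties]
    iy, ix = ties[int(np.argmin(mags))]
    dy, dx = float(sub_lags[iy]), float(sub_lags[ix])

    def corr_at(ly: int, lx: int) -> float:
        # divide out the zero-padding overlap envelope, which otherwise
        # skews the three-point sub-pixel fit toward zero displacement
        env = (w - abs(ly)) * (w - abs(lx))
        return float(corr[ly % size, lx % size]) / max(env, 1)

    ly, lx = int(sub_lags[iy]), int(sub_lags[ix])
    if abs(ly) < half:
        dy += _subpixel_offset(corr_at(ly - 1, lx), corr_at(ly, lx), corr_at(ly + 1, lx), method)
    if abs(lx) < half:
        dx += _subpixel_offset(corr_at(ly, lx - 1), corr_at(ly, lx), corr_at(ly, lx + 1), method)
    return dx, dy, True


def compute_piv_pair(frame_a: np.ndarray, frame_b: np.ndarray, config: PIVConfig) -> VelocityField:
    """Velocity field (um/h) from one consecutive frame pair."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    w = config.window_size
    if min(a.shape) < w:
        raise ValueError("frames smaller than the interrogation window")
    step = max(1, int(round(w * (1.0 - config.overlap_fraction))))
    ys = np.arange(0, a.shape[0] - w + 1, step)
    xs = np.arange(0, a.shape[1] - w + 1, step)
    u = np.zeros((len(ys), len(xs)))
    v = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    scale = config.pixel_size / (config.frame_interval / 60.0)  # um/h per px/frame
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            win_a = a[y0:y0 + w, x0:x0 + w]
            dx, dy, ok = _window_displacement(
                win_a, b[y0:y0 + w, x0:x0 + w], config.subpixel_method
            )
            if ok:
                # second pass with discrete window offset: re-correlate with
                # the window pair offset by the integer displacement,
                # removing the loss-of-pairs asymmetry of the first pass.
                # Near the frame border the A window shifts oppositely so
                # the full offset is always realized.
                idy, idx = int(round(dy)), int(round(dx))
                hmax, wmax = a.shape[0] - w, a.shape[1] - w
                y_lo, y_hi = max(0, -idy), min(hmax, hmax - idy)
                x_lo, x_hi = max(0, -idx), min(wmax, wmax - idx)
                if (idy, idx) != (0, 0) and y_lo <= y_hi and x_lo <= x_hi:
                    ay = int(np.clip(y0, y_lo, y_hi))
                    ax = int(np.clip(x0, x_lo, x_hi))
                    by, bx = ay + idy, ax + idx
                    dx2, dy2, ok2 = _window_displacement(
                        a[ay:ay + w, ax:ax + w],
                        b[by:by + w, bx:bx + w],
                        config.subpixel_method,
                    )
                    if ok2:
                        dx, dy = idx + dx2, idy + dy2
            valid[i, j] = ok
            if ok:
                u[i, j] = dx * scale
                v[i, j] = dy * scale
    return VelocityField(
        grid_x=(xs + w / 2.0) * config.pixel_size,
        grid_y=(ys + w / 2.0) * config.pixel_size,
        u=u,
        v=v,
        valid=valid,
    )


def validate_field(field: VelocityField, config: PIVConfig) -> VelocityField:
    """Normalized-median outlier test (3x3 neighbourhood).

    A vector whose residual against the neighbourhood median, normalized by
    the median absolute neighbour fluctuation, exceeds
    ``config.outlier_threshold`` is replaced by the neighbourhood median and
    flagged as interpolated. Fields smaller than 3x3 are returned unchanged
    with a warning status.
    """
    ny, nx = field.u.shape
    if ny < 3 or nx < 3:
        return replace(field, status="too-small-for-validation")
    eps = 0.1 * config.pixel_size / (config.frame_interval / 60.0)  # 0.1 px/frame in um/h
    u, v = field.u.copy(), field.v.copy()
    interp = field.interpolated.copy()
    for i in range(ny):
        for j in range(nx):
            if not field.valid[i, j]:
                continue
            i0, i1 = max(i - 1, 0), min(i + 2, ny)
            j0, j1 = max(j - 1, 0), min(j + 2, nx)
            nb_mask = field.valid[i0:i1, j0:j1].copy()
            nb_mask[i - i0, j - j0] = False
            if nb_mask.sum() < 3:
                continue
            nu = field.u[i0:i1, j0:j1][nb_mask]
            nv = field.v[i0:i1, j0:j1][nb_mask]
            mu, mv = np.median(nu), np.median(nv)
            ru = abs(field.u[i, j] - mu) / (np.median(np.abs(nu - mu)) + eps)
            rv = abs(field.v[i, j] - mv) / (np.median(np.abs(nv - mv)) + eps)
            if np.hypot(ru, rv) > config.outlier_threshold:
                u[i, j], v[i, j] = mu, mv
                interp[i, j] = True
    return replace(field, u=u, v=v, interpolated=interp)


def piv_movie(stack: np.ndarray, config: PIVConfig) -> list[VelocityField]:
    """One validated velocity field per consecutive frame pair."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("piv_movie needs a stack of at least 2 frames")
    fields = []
    for k in range(stack.shape[0] - 1):
        f = compute_piv_pair(stack[k], stack[k + 1], config)
        f = validate_field(f, config)
        f.frame_index = k
        fields.append(f)
    return fields
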
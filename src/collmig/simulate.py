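"""Synthetic scratch-wounded monolayer: active-particle model and renderers.

The simulator is a Vicsek-style active-particle model of a confluent sheet
with a vertical cell-free stripe (the scratch wound) centered in the box.
Each cell carries a position and a heading; per time step the heading is
updated toward the circular mean of neighbour headings (weight
``alignment_strength``), pulled toward the inward wound normal for cells
within a fixed 60 um band outside the wound edge (weight ``wound_bias``,
mirroring the front-cell band of wound-healing analysis), perturbed by
Gaussian angular noise, and the cell advances by ``speed_v0 * dt`` along
its heading. Cells repel along their center line when closer than a
hard-core exclusion distance, and the box has reflective boundaries so the
wound geometry stays meaningful in a bounded field of view.

The model is deliberately kinematic: it emulates only the signatures the
analysis pipeline measures (speeds of a few nm/s, tunable velocity
alignment, a closing wound) and encodes no claim about the biology that
produces them.

Rendering produces the image modalities the downstream modules consume:
nuclei as Gaussian spots (for detection/tracking), cell bodies as frozen
per-cell speckle disks that translate with the cell (for PIV and wound
segmentation — the speckle pattern is fixed at cell creation so the
correlation stage sees a translating texture), a forward model for
two-channel generalized-polarization imaging, and ellipse "puncta" images
with known areas for the morphometry filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

from .tracking import Track

__all__ = [
    "SimulationConfig",
    "RenderConfig",
    "BlobGroundTruth",
    "FRONT_BAND_UM",
    "HARD_CORE_UM",
    "simulate_monolayer",
    "render_nuclei_frames",
    "render_texture_frames",
    "make_gp_pair",
    "make_blob_image",
]

FRONT_BAND_UM = 60.0  # wound-bias band: ~three nuclear diameters
HARD_CORE_UM = 5.0  # volume-exclusion surrogate


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the wounded-monolayer generator.

    Defaults emulate the live-imaging conditions the pipeline is built for:
    10-min frame interval over 16 h, single-cell speeds in the 2-7 nm/s
    range (default 5 nm/s), and a vertical ~200 um scratch in a confluent
    sheet, scaled to a 600 x 400 um field of view.

    initial_heading: if given, every cell starts with this heading
    (radians); otherwise headings are uniform random. min_spacing sets the
    initial-placement exclusion distance (also the hard-core distance used
    during the run, floored at 5 um).
    """

    n_cells: int = 600
    box_width: float = 600.0  # um
    box_height: float = 400.0  # um
    wound_half_width: float = 100.0  # um; stripe centered at box_width / 2
    speed_v0: float = 5.0  # nm/s
    alignment_strength: float = 0.6  # dimensionless in [0, 1]
    interaction_radius: float = 30.0  # um
    heading_noise: float = 0.8  # rad, std of per-step angular noise
    wound_bias: float = 0.3  # dimensionless in [0, 1]
    dt: float = 10.0  # minutes
    n_steps: int = 96  # 16 h at 10 min
    seed: int = 0
    initial_heading: float | None = None
    min_spacing: float = HARD_CORE_UM  # um

    def __post_init__(self) -> None:
        for name in ("box_width", "box_height", "wound_half_width", "speed_v0",
                     "interaction_radius", "dt", "min_spacing"):
            val = getattr(self, name)
            if not math.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and positive, got {val!r}")
        for name in ("alignment_strength", "wound_bias"):
            val = getattr(self, name)
            if not math.isfinite(val) or not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val!r}")
        if not math.isfinite(self.heading_noise) or self.heading_noise < 0:
            raise ValueError("heading_noise must be finite and non-negative")
        if self.n_cells < 1 or self.n_steps < 1:
            raise ValueError("n_cells and n_steps must be at least 1")
        if 2 * self.wound_half_width >= self.box_width:
            raise ValueError("wound stripe must be narrower than the box")

    @property
    def step_um(self) -> float:
        """Distance a cell advances per step: nm/s * minutes -> um."""
        return self.speed_v0 * self.dt * 60.0 / 1000.0


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters shared by the nuclei and texture channels."""

    pixel_size: float = 1.0  # um/px
    image_width: int = 600  # px
    image_height: int = 400  # px
    nucleus_sigma: float = 2.0  # um
    texture_grain: float = 2.0  # um, speckle correlation scale
    cell_radius: float = 12.0  # um, texture disk radius
    background_level: float = 200.0
    signal_level: float = 2000.0
    noise_sigma: float = 20.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


def _initial_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions outside the wound stripe with min-spacing rejection."""
    cx = config.box_width / 2.0
    lo, hi = cx - config.wound_half_width, cx + config.wound_half_width
    placed: list[np.ndarray] = []
    tree_pts: np.ndarray | None = None
    attempts = 0
    max_attempts = 200 * config.n_cells
    while len(placed) < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place cells at the requested spacing; "
                "reduce n_cells or min_spacing"
            )
        x = rng.uniform(0.0, config.box_width)
        if lo < x < hi:
            continue
        y = rng.uniform(0.0, config.box_height)
        p = np.array([x, y])
        if placed:
            if tree_pts is None or len(tree_pts) != len(placed):
                tree_pts = np.array(placed)
            d = np.linalg.norm(tree_pts - p, axis=1).min()
            if d < config.min_spacing:
                continue
        placed.append(p)
        tree_pts = None
    return np.array(placed)


def _reflect(pos: np.ndarray, heading: np.ndarray, w: float, h: float) -> None:
    """Reflective box boundaries, in place."""
    over_x = pos[:, 0] < 0
    pos[over_x, 0] = -pos[over_x, 0]
    heading[over_x] = np.pi - heading[over_x]
    over_x = pos[:, 0] > w
    pos[over_x, 0] = 2 * w - pos[over_x, 0]
    heading[over_x] = np.pi - heading[over_x]
    over_y = pos[:, 1] < 0
    pos[over_y, 1] = -pos[over_y, 1]
    heading[over_y] = -heading[over_y]
    over_y = pos[:, 1] > h
    pos[over_y, 1] = 2 * h - pos[over_y, 1]
    heading[over_y] = -heading[over_y]


def simulate_monolayer(config: SimulationConfig) -> list[Track]:
    """Run the active-particle model; one Track per cell, n_steps + 1 points.

    Deterministic: identical config (including seed) gives bit-identical
    trajectories from the single global RNG stream. Cell number is conserved
    (no division or death).
    """
    rng = np.random.default_rng(config.seed)
    pos = _initial_positions(config, rng)
    if config.initial_heading is not None:
        heading = np.full(config.n_cells, float(config.initial_heading))
    else:
        heading = rng.uniform(-np.pi, np.pi, config.n_cells)
    hard_core = max(config.min_spacing, HARD_CORE_UM)
    cx = config.box_width / 2.0
    stripe_lo = cx - config.wound_half_width
    stripe_hi = cx + config.wound_half_width
    alpha, bias = config.alignment_strength, config.wound_bias
    traj = np.empty((config.n_steps + 1, config.n_cells, 2))
    traj[0] = pos

    for step in range(config.n_steps):
        # hard-core exclusion: push overlapping pairs apart along their
        # center line before the heading update
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(hard_core):
            delta = pos[j] - pos[i]
            d = np.linalg.norm(delta)
            if d < 1e-9:
                ang = rng.uniform(-np.pi, np.pi)
                delta = np.array([np.cos(ang), np.sin(ang)])
                d = 1.0
            push = 0.5 * (hard_core - d) * delta / d
            pos[i] -= push
            pos[j] += push
        np.clip(pos[:, 0], 0.0, config.box_width, out=pos[:, 0])
        np.clip(pos[:, 1], 0.0, config.box_height, out=pos[:, 1])

        # alignment: blend own heading with the mean neighbour heading
        hx, hy = np.cos(heading), np.sin(heading)
        if alpha > 0:
            tree = cKDTree(pos)
            neighbours = tree.query_ball_point(pos, config.interaction_radius)
            mx, my = hx.copy(), hy.copy()
            for i, idx in enumerate(neighbours):
                idx = [k for k in idx if k != i]
                if idx:
                    mx[i] = hx[idx].mean()
                    my[i] = hy[idx].mean()
            vx = (1.0 - alpha) * hx + alpha * mx
            vy = (1.0 - alpha) * hy + alpha * my
        else:
            vx, vy = hx, hy

        # wound bias: cells within the front band outside the stripe, and
        # cells already inside it, are pulled along the inward wound normal
        # (toward the stripe midline, where opposing fronts meet)
        if bias > 0:
            left = (pos[:, 0] >= stripe_lo - FRONT_BAND_UM) & (pos[:, 0] < cx)
            right = (pos[:, 0] >= cx) & (pos[:, 0] <= stripe_hi + FRONT_BAND_UM)
            norm = np.hypot(vx, vy)
            norm[norm < 1e-12] = 1.0
            vx, vy = vx / norm, vy / norm
            vx[left] = (1.0 - bias) * vx[left] + bias * 1.0
            vx[right] = (1.0 - bias) * vx[right] + bias * (-1.0)
            vy[left] *= 1.0 - bias
            vy[right] *= 1.0 - bias

        heading = np.arctan2(vy, vx)
        if config.heading_noise > 0:
            heading = heading + rng.normal(0.0, config.heading_noise, config.n_cells)

        pos = pos + config.step_um * np.column_stack([np.cos(heading), np.sin(heading)])
        _reflect(pos, heading, config.box_width, config.box_height)
        traj[step + 1] = pos

    frames = np.arange(config.n_steps + 1)
    return [
        Track(
            track_id=i,
            frames=frames,
            t_min=frames * config.dt,
            x_um=traj[:, i, 0].copy(),
            y_um=traj[:, i, 1].copy(),
        )
        for i in range(config.n_cells)
    ]


def _positions_at(tracks: list[Track], frame: int) -> np.ndarray:
    pts = []
    for tr in tracks:
        hit = np.nonzero(tr.frames == frame)[0]
        if len(hit):
            pts.append([tr.x_um[hit[0]], tr.y_um[hit[0]]])
    return np.array(pts) if pts else np.empty((0, 2))


def _n_frames(tracks: list[Track]) -> int:
    return max((int(tr.frames.max()) for tr in tracks), default=-1) + 1


def render_nuclei_frames(
    tracks: list[Track], render_config: RenderConfig, seed: int = 0
) -> np.ndarray:
    """Render the nuclei channel: a Gaussian spot per cell plus Gaussian
    noise, quantized to the configured bit depth."""
    rc = render_config
    rng = np.random.default_rng(seed)
    n_frames = _n_frames(tracks)
    stack = np.empty((max(n_frames, 1), rc.image_height, rc.image_width), dtype=rc.dtype)
    sigma_px = rc.nucleus_sigma / rc.pixel_size
    half = int(np.ceil(4 * sigma_px))
    for f in range(max(n_frames, 1)):
        img = np.full((rc.image_height, rc.image_width), float(rc.background_level))
        for x_um, y_um in _positions_at(tracks, f):
            cx, cy = x_um / rc.pixel_size, y_um / rc.pixel_size
            x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            x0c, x1c = max(x0, 0), min(x1, rc.image_width)
            y0c, y1c = max(y0, 0), min(y1, rc.image_height)
            if x0c >= x1c or y0c >= y1c:
                continue
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            img[y0c:y1c, x0c:x1c] += rc.signal_level * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma_px**2)
            )
        if rc.noise_sigma > 0:
            img += rng.normal(0.0, rc.noise_sigma, img.shape)
        stack[f] = np.clip(np.round(img), 0, rc.max_value).astype(rc.dtype)
    return stack


def _speckle_patch(rc: RenderConfig, rng: np.random.Generator) -> np.ndarray:
    """Frozen per-cell texture: smoothed positive speckle on a disk."""
    r_px = rc.cell_radius / rc.pixel_size
    size = 2 * int(np.ceil(r_px)) + 1
    raw = rng.uniform(0.0, 1.0, (size, size))
    grain_px = max(rc.texture_grain / rc.pixel_size, 0.5)
    tex = gaussian_filter(raw, grain_px / 2.0, mode="wrap")
    lo, hi = tex.min(), tex.max()
    tex = (tex - lo) / (hi - lo) if hi > lo else np.full_like(tex, 0.5)
    yy, xx = np.mgrid[:size, :size] - (size - 1) / 2.0
    disk = (xx**2 + yy**2) <= r_px**2
    patch = np.zeros((size, size))
    patch[disk] = (0.25 + 0.75 * tex[disk]) * rc.signal_level
    return patch


def render_texture_frames(
    tracks: list[Track], render_config: RenderConfig, seed: int = 0
) -> np.ndarray:
    """Render the phase-contrast-like channel.

    Each cell is a disk of speckle texture frozen at cell creation that
    rigidly translates with the cell (sub-pixel placement by bilinear
    shifting); the cell-free wound stripe is plain low-variance background.
    Overlapping cells combine by maximum, keeping local variance bounded.
    """
    rc = render_config
    rng = np.random.default_rng(seed)
    n_frames = _n_frames(tracks)
    patches = {tr.track_id: _speckle_patch(rc, rng) for tr in tracks}
    stack = np.empty((max(n_frames, 1), rc.image_height, rc.image_width), dtype=rc.dtype)
    for f in range(max(n_frames, 1)):
        img = np.full((rc.image_height, rc.image_width), float(rc.background_level))
        for tr in tracks:
            hit = np.nonzero(tr.frames == f)[0]
            if not len(hit):
                continue
            patch = patches[tr.track_id]
            size = patch.shape[0]
            cx = tr.x_um[hit[0]] / rc.pixel_size
            cy = tr.y_um[hit[0]] / rc.pixel_size
            x0 = int(np.floor(cx)) - size // 2
            y0 = int(np.floor(cy)) - size // 2
            fx, fy = cx - np.floor(cx), cy - np.floor(cy)
            shifted = nd_shift(patch, (fy, fx), order=1, mode="constant", cval=0.0)
            x0c, x1c = max(x0, 0), min(x0 + size, rc.image_width)
            y0c, y1c = max(y0, 0), min(y0 + size, rc.image_height)
            if x0c >= x1c or y0c >= y1c:
                continue
            view = img[y0c:y1c, x0c:x1c]
            np.maximum(
                view,
                rc.background_level + shifted[y0c - y0:y1c - y0, x0c - x0:x1c - x0],
                out=view,
            )
        if rc.noise_sigma > 0:
            img += rng.normal(0.0, rc.noise_sigma, img.shape)
        stack[f] = np.clip(np.round(img), 0, rc.max_value).astype(rc.dtype)
    return stack


def make_gp_pair(
    gp_map: np.ndarray,
    total_intensity: np.ndarray | float,
    G: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model for ratiometric GP imaging.

    Inverts the GP ratio exactly: with I445 = T (1 + GP) / 2 and
    I525 = T (1 - GP) / (2 G), the ratio (I445 - G I525) / (I445 + G I525)
    applied to the noise-free pair returns ``gp_map`` identically (the
    denominator equals T). Gaussian noise of std ``noise_sigma`` is added
    to each channel independently.
    """
    gp = np.asarray(gp_map, dtype=float)
    if np.any(np.abs(gp) >= 1.0):
        raise ValueError("gp_map values must lie strictly inside (-1, 1)")
    T = np.broadcast_to(np.asarray(total_intensity, dtype=float), gp.shape)
    if np.any(T <= 0):
        raise ValueError("total_intensity must be positive")
    if G <= 0:
        raise ValueError("G must be positive")
    i445 = T * (1.0 + gp) / 2.0
    i525 = T * (1.0 - gp) / (2.0 * G)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        i445 = i445 + rng.normal(0.0, noise_sigma, gp.shape)
        i525 = i525 + rng.normal(0.0, noise_sigma, gp.shape)
    return i445, i525


@dataclass
class BlobGroundTruth:
    """True areas (um^2) and centers of the rendered puncta."""

    areas_um2: np.ndarray
    centers_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def count_above(self, threshold_um2: float) -> int:
        """Number of puncta with area strictly greater than the threshold."""
        return int(np.sum(self.areas_um2 > threshold_um2))


def make_blob_image(
    blob_areas_um2: list[float],
    pixel_size: float,
    image_shape: tuple[int, int] = (200, 200),
    background_level: float = 10.0,
    signal_level: float = 200.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, BlobGroundTruth]:
    """Bright ellipses of the requested areas on a noisy background.

    Puncta are placed without overlap (rejection sampling; an over-crowded
    request is rejected with an error). The ground truth records the
    requested areas so any area threshold can be evaluated against it.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    img = np.full((h, w), float(background_level))
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for area in blob_areas_um2:
        if area <= 0:
            raise ValueError("blob areas must be positive")
        area_px = area / pixel_size**2
        ratio = rng.uniform(0.6, 1.0)
        r_major = np.sqrt(area_px / (np.pi * ratio))
        r_minor = r_major * ratio
        if 2 * (r_major + 2) >= min(h, w):
            raise ValueError(
                "could not place puncta without overlap: over-crowded request"
            )
        placed = False
        for _ in range(500):
            cy = rng.uniform(r_major + 2, h - r_major - 2)
            cx = rng.uniform(r_major + 2, w - r_major - 2)
            if all(
                np.hypot(cy - py, cx - px) > r_major + pr + 3
                for (py, px), pr in zip(centers, radii)
            ):
                placed = True
                break
        if not placed:
            raise ValueError("could not place puncta without overlap: over-crowded request")
        rr, cc = draw_ellipse(cy, cx, r_minor, r_major,
                              shape=(h, w), rotation=rng.uniform(0, np.pi))
        img[rr, cc] = signal_level
        centers.append((cy, cx))
        radii.append(r_major)
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape)
    truth = BlobGroundTruth(
        areas_um2=np.asarray(blob_areas_um2, dtype=float),
        centers_px=np.array(centers) if centers else np.empty((0, 2)),
    )
    return img, truth
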
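"""Ratiometric generalized-polarization (GP) imaging of membrane order.

An environment-sensitive membrane dye shifts its emission toward the short
wavelength band as lipid packing becomes more ordered, so the normalized
two-band ratio

    GP = (I445 - G * I525) / (I445 + G * I525)

reports membrane order per pixel; higher GP means stiffer, more gel-like
packing. G is an instrument/dye correction factor obtained from a solvent
reference measurement:

    G = (G_ref + G_ref*G_m - G_m - 1) / (G_m + G_ref*G_m - G_ref - 1)

with G_ref the dye's literature reference value (0.207 by default) and G_m
the GP measured for the dye in DMSO on the instrument at hand. Pixels whose
denominator falls below an intensity floor are masked invalid so dim noise
does not masquerade as order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GPResult", "G_REF_DEFAULT", "compute_g_factor", "gp_map", "interface_gp"]

G_REF_DEFAULT = 0.207


@dataclass
class GPResult:
    gp: np.ndarray  # per-pixel GP, in [-1, 1] where valid
    valid: np.ndarray  # bool mask
    G: float
    intensity_floor: float


def compute_g_factor(G_m: float, G_ref: float = G_REF_DEFAULT) -> float:
    """Correction factor from the solvent reference measurement.

    The expression has a pole at G_m = 1 and yields non-positive G outside
    (-1, 1), so G_m must lie strictly inside (-1, 1). G_m equal to G_ref
    gives exactly 1 (no correction needed).
    """
    if not -1.0 < G_m < 1.0:
        raise ValueError(
            f"G_m must lie strictly in (-1, 1); got {G_m!r} "
            "(the formula has poles at +-1)"
        )
    num = G_ref + G_ref * G_m - G_m - 1.0
    den = G_m + G_ref * G_m - G_ref - 1.0
    G = num / den
    if G <= 0:  # pragma: no cover - excluded by the domain check above
        raise ValueError(f"computed correction factor is non-positive: {G}")
    return G


def _default_floor(i445: np.ndarray, i525: np.ndarray) -> float:
    # 1% of the bit-depth maximum for integer images; 1% of the observed
    # total intensity otherwise
    for img in (i445, i525):
        if np.issubdtype(img.dtype, np.integer):
            return 0.01 * float(np.iinfo(img.dtype).max)
    return 0.01 * float(np.maximum(i445 + i525, 0).max())


def gp_map(
    i445: np.ndarray,
    i525: np.ndarray,
    G: float = 1.0,
    intensity_floor: float | None = None,
) -> GPResult:
    """Per-pixel GP from the two emission bands.

    Pixels with I445 + G*I525 below the intensity floor are flagged invalid
    (their GP is set to 0 and excluded from summaries).
    """
    if np.shape(i445) != np.shape(i525):
        raise ValueError("channel images must have the same shape")
    if G <= 0:
        raise ValueError("G must be positive")
    a = np.asarray(i445)
    b = np.asarray(i525)
    if intensity_floor is None:
        intensity_floor = _default_floor(a, b)
    a = a.astype(float)
    b = b.astype(float)
    denom = a + G * b
    valid = denom >= intensity_floor
    gp = np.zeros_like(denom)
    np.divide(a - G * b, denom, out=gp, where=valid)
    return GPResult(gp=gp, valid=valid, G=G, intensity_floor=float(intensity_floor))


def interface_gp(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    mask: np.ndarray,
    G: float = 1.0,
    intensity_floor: float | None = None,
    mode: str = "subtract",
) -> np.ndarray:
    """GP time course at a cell-cell interface ROI, normalized to t0.

    For each (I445, I525) pair the mean valid GP inside ``mask`` is taken;
    the series is then normalized to its initial value — by subtraction
    (default; the series starts at 0 and reports the GP change) or by
    division (``mode="divide"``). Raises if the mask never overlaps a valid
    pixel.
    """
    if mode not in ("subtract", "divide"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("interface mask is empty")
    means = []
    for i445, i525 in pairs:
        res = gp_map(i445, i525, G, intensity_floor)
        sel = mask & res.valid
        if not sel.any():
            raise ValueError("interface mask contains no valid pixel")
        means.append(float(res.gp[sel].mean()))
    series = np.array(means)
    if mode == "subtract":
        return series - series[0]
    if series[0] == 0:
        raise ValueError("cannot divide by zero initial GP")
    return series / series[0]
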
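"""Shared study conditions for the analysis scripts.

Two illumination-like conditions differing only in the cell-cell coupling:
'adhesive' (strong velocity alignment, as when intercellular adhesions are
switched on) and 'nonadhesive' (weak alignment). Everything else — speed,
noise, wound geometry, frame interval — is held fixed.
"""

from pathlib import Path

from collmig.simulate import RenderConfig, SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

PIXEL_SIZE = 2.0  # um/px
FRAME_INTERVAL_MIN = 10.0

CONDITIONS = {
    "adhesive": SimulationConfig(alignment_strength=0.9, n_steps=48, seed=2024),
    "nonadhesive": SimulationConfig(alignment_strength=0.1, n_steps=48, seed=2024),
}

RENDER = RenderConfig(
    pixel_size=PIXEL_SIZE,
    image_width=300,
    image_height=200,
    noise_sigma=10.0,
)

NUCLEI_RENDER = RenderConfig(
    pixel_size=PIXEL_SIZE,
    image_width=300,
    image_height=200,
    nucleus_sigma=4.0,
    noise_sigma=5.0,
)
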
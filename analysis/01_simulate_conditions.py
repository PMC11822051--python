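#!/usr/bin/env python
"""Simulate the two adhesion conditions and render their image stacks.

Generates ground-truth trajectories for an adhesive (strongly aligned) and
a nonadhesive (weakly aligned) wounded monolayer under otherwise identical
conditions, renders phase-contrast-like texture and nuclei channels, and
writes tracks (CSV), stacks (TIFF) and configs (YAML) under results/sim/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONDITIONS, NUCLEI_RENDER, RENDER, RESULTS

from collmig.io import write_config_yaml, write_stack, write_tracks_csv
from collmig.simulate import render_nuclei_frames, render_texture_frames, simulate_monolayer


def main() -> None:
    out = RESULTS / "sim"
    out.mkdir(parents=True, exist_ok=True)
    for name, cfg in CONDITIONS.items():
        print(f"[{name}] simulating {cfg.n_cells} cells, "
              f"{cfg.n_steps} steps of {cfg.dt} min (alignment {cfg.alignment_strength})")
        tracks = simulate_monolayer(cfg)
        write_tracks_csv(out / f"{name}_tracks.csv", tracks)
        write_config_yaml(out / f"{name}_config.yaml", cfg)
        texture = render_texture_frames(tracks, RENDER, seed=cfg.seed + 1)
        write_stack(out / f"{name}_texture.tif", texture)
        nuclei = render_nuclei_frames(tracks, NUCLEI_RENDER, seed=cfg.seed + 2)
        write_stack(out / f"{name}_nuclei.tif", nuclei)
        print(f"[{name}] wrote tracks, texture and nuclei stacks "
              f"({texture.shape[0]} frames of {texture.shape[1]}x{texture.shape[2]} px)")


if __name__ == "__main__":
    main()
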
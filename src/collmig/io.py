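"""File I/O: multi-page TIFF stacks, track/field CSV, YAML configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .piv import VelocityField
from .simulate import RenderConfig, SimulationConfig
from .tracking import Track

__all__ = [
    "write_stack",
    "read_stack",
    "tracks_to_frame",
    "write_tracks_csv",
    "read_tracks_csv",
    "fields_to_frame",
    "write_fields_csv",
    "write_config_yaml",
    "read_config_yaml",
]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, stack)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, t, x, y in zip(tr.frames, tr.t_min, tr.x_um, tr.y_um):
            rows.append((tr.track_id, int(f), float(t), float(x), float(y)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"])


def write_tracks_csv(path: str | Path, tracks: list[Track]) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                t_min=grp["t_min"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
            )
        )
    return out


def fields_to_frame(fields: list[VelocityField]) -> pd.DataFrame:
    rows = []
    for f in fields:
        for i, gy in enumerate(f.grid_y):
            for j, gx in enumerate(f.grid_x):
                rows.append(
                    (f.frame_index, float(gx), float(gy), float(f.u[i, j]),
                     float(f.v[i, j]), bool(f.valid[i, j]), bool(f.interpolated[i, j]))
                )
    return pd.DataFrame(
        rows,
        columns=["frame_index", "grid_x_um", "grid_y_um", "u_um_per_h",
                 "v_um_per_h", "valid", "interpolated"],
    )


def write_fields_csv(path: str | Path, fields: list[VelocityField]) -> None:
    fields_to_frame(fields).to_csv(path, index=False)


def write_config_yaml(path: str | Path, config: SimulationConfig | RenderConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_config_yaml(path: str | Path, kind: str = "simulation"):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cls = {"simulation": SimulationConfig, "render": RenderConfig}[kind]
    return cls(**data)
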
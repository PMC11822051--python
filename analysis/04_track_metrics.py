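#!/usr/bin/env python
"""Single-cell tracking and per-cell motility metrics.

Detects nuclei in the rendered nuclei channel with a Laplacian-of-Gaussian
detector, links them into trajectories (greedy nearest neighbour, no gap
closing), applies the trajectory filters (tracks shorter than four steps
excluded), and computes straightness, median speed (nm/s), and orientation
relative to the inward wound normal, split by front/rear band. Outputs
under results/tracks/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONDITIONS, FRAME_INTERVAL_MIN, PIXEL_SIZE, RESULTS

from collmig.io import read_stack
from collmig.tracking import detect_nuclei, filter_tracks, link_tracks, track_metrics
from collmig.wound import classify_front_rear, segment_wound


def main() -> None:
    out = RESULTS / "tracks"
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name in CONDITIONS:
        nuclei = read_stack(RESULTS / "sim" / f"{name}_nuclei.tif")
        texture = read_stack(RESULTS / "sim" / f"{name}_texture.tif")
        detections = []
        for f, frame in enumerate(nuclei):
            dets = detect_nuclei(frame, sigma_um=4.0, pixel_size=PIXEL_SIZE,
                                 threshold=100.0)
            detections.append([d.__class__(f, d.x_um, d.y_um, d.response)
                               for d in dets])
        tracks = link_tracks(detections, max_displacement_um=8.0,
                             frame_interval_min=FRAME_INTERVAL_MIN)
        tracks = filter_tracks(tracks, min_steps=4)

        wound0 = segment_wound(texture[0], PIXEL_SIZE)
        starts = np.array([[t.x_um[0], t.y_um[0]] for t in tracks])
        # inward normal points toward the wound: +x left of it, -x right
        cx = texture.shape[2] * PIXEL_SIZE / 2.0
        rows = []
        for t, (x0, _) in zip(tracks, starts):
            normal = (1.0, 0.0) if x0 < cx else (-1.0, 0.0)
            m = track_metrics(t, wound_normal=normal)
            rows.append({
                "track_id": t.track_id,
                "n_steps": t.n_steps,
                "straightness": m.straightness,
                "median_speed_nm_s": m.median_speed_nm_s,
                "orientation_deg": m.orientation_deg,
            })
        df = pd.DataFrame(rows)
        fr = classify_front_rear(starts, wound0.mask, PIXEL_SIZE)
        df["front_rear"] = fr.labels
        df.to_csv(out / f"{name}_metrics.csv", index=False)

        front = df[df["front_rear"] == "front"]
        summary[name] = {
            "n_tracks": len(df),
            "n_detections_frame0": len(detections[0]),
            "median_straightness": float(df["straightness"].median()),
            "median_speed_nm_s": float(df["median_speed_nm_s"].median()),
            "front_median_straightness": float(front["straightness"].median()),
        }
        print(f"[{name}] {len(df)} tracks kept; median straightness "
              f"{summary[name]['median_straightness']:.2f}, median speed "
              f"{summary[name]['median_speed_nm_s']:.1f} nm/s "
              f"(front cells: straightness {summary[name]['front_median_straightness']:.2f})")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
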
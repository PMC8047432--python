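"""Readers and writers for the pipeline's on-disk formats.

Section images travel as two-page TIFF (page 0 = dystrophin, page 1 =
laminin, uint16 AU), label maps as integer TIFF, ground truth as JSON,
lane profiles and force series as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth, LaneProfile, SectionImage


def write_section_tiff(path: str | Path, image: SectionImage) -> None:
    stack = np.stack([np.clip(np.round(image.dystrophin), 0, 65535),
                      np.clip(np.round(image.laminin), 0, 65535)]).astype(np.uint16)
    tifffile.imwrite(str(path), stack, metadata={
        "axes": "CYX", "channel0": "dystrophin", "channel1": "laminin",
        "pixel_size_um": image.pixel_size, "sample_id": image.sample_id,
        "exposure_batch": image.exposure_batch})


def read_section_tiff(path: str | Path, **metadata) -> SectionImage:
    stack = tifffile.imread(str(path))
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError("expected a two-channel (dystrophin, laminin) stack")
    return SectionImage(dystrophin=stack[0].astype(float),
                        laminin=stack[1].astype(float), **metadata)


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), labels.astype(np.int32))


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    payload = {
        "cutoff": gt.cutoff,
        "n_positive": gt.n_positive,
        "n_total": gt.n_total,
        "true_intensity_ratio": gt.true_intensity_ratio,
        "per_fiber_fraction": {str(k): v for k, v in gt.per_fiber_fraction.items()},
        "per_fiber_positive": {str(k): bool(v) for k, v in gt.per_fiber_positive.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_lane_csv(path: str | Path, profile: LaneProfile) -> None:
    pd.DataFrame({"position": profile.positions,
                  "intensity": profile.intensities}).to_csv(path, index=False)


def read_lane_csv(path: str | Path, lane_id: str = "lane0") -> LaneProfile:
    df = pd.read_csv(path)
    return LaneProfile(positions=df["position"].to_numpy(float),
                       intensities=df["intensity"].to_numpy(float),
                       lane_id=lane_id)


def write_force_csv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
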
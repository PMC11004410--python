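"""Readers and writers for the pipeline's on-disk formats.

Movies and tiles travel as multi-page grayscale TIFF, tabular results as
CSV, ground truth and reports as JSON, configuration as YAML.  Every
writer here has a matching reader that round-trips values exactly (within
the float precision of the container).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack
from .detect import SpotDetection
from .events import ExocytosisEvent
from .simulate import BindingCurve, TirfGroundTruth
from .stats import FluorescenceDataset
from .track import Track

__all__ = [
    "write_stack", "read_stack",
    "write_detections", "read_detections",
    "write_tracks", "write_track_summary",
    "write_events",
    "write_dataset", "read_dataset",
    "write_binding_curve", "read_binding_curve",
    "write_ground_truth",
    "write_json", "read_json",
]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    meta = {}
    if stack.pixel_size_nm is not None:
        meta["pixel_size_nm"] = stack.pixel_size_nm
    if stack.frame_interval_s is not None:
        meta["frame_interval_s"] = stack.frame_interval_s
    tifffile.imwrite(path, stack.data, metadata=meta)


def read_stack(path: str | Path, pixel_size_nm: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return ImageStack(
        data,
        pixel_size_nm=pixel_size_nm or meta.get("pixel_size_nm"),
        frame_interval_s=frame_interval_s or meta.get("frame_interval_s"),
    )


_DET_COLUMNS = ["frame", "x", "y", "area_px", "diameter_nm", "circularity",
                "peak", "mean"]


def detections_to_frame(per_frame: list[list[SpotDetection]]) -> pd.DataFrame:
    rows = [(d.frame_index, d.x, d.y, d.area_px, d.equivalent_diameter_nm,
             d.circularity, d.peak_intensity, d.mean_intensity)
            for dets in per_frame for d in dets]
    return pd.DataFrame(rows, columns=_DET_COLUMNS)


def write_detections(path: str | Path, per_frame: list[list[SpotDetection]]) -> None:
    detections_to_frame(per_frame).to_csv(path, index=False)


def read_detections(path: str | Path, n_frames: int | None = None) -> list[list[SpotDetection]]:
    df = pd.read_csv(path)
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    per_frame: list[list[SpotDetection]] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        per_frame[int(row.frame)].append(SpotDetection(
            frame_index=int(row.frame), x=row.x, y=row.y,
            area_px=int(row.area_px), equivalent_diameter_nm=row.diameter_nm,
            circularity=row.circularity, peak_intensity=row.peak,
            mean_intensity=row.mean))
    return per_frame


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    rows = [(tr.track_id, d.frame_index, d.x, d.y, d.peak_intensity)
            for tr in tracks for d in tr.detections]
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y",
                                "peak_intensity"]).to_csv(path, index=False)


def write_track_summary(path: str | Path, tracks: list[Track]) -> None:
    rows = [(tr.track_id, len(tr), tr.alpha, tr.is_subdiffusive)
            for tr in tracks]
    pd.DataFrame(rows, columns=["track_id", "length", "alpha",
                                "is_subdiffusive"]).to_csv(path, index=False)


def write_events(path: str | Path, events: list[ExocytosisEvent],
                 fov_id: str = "fov0") -> None:
    rows = [(fov_id, e.track_id, e.event_frame, e.x, e.y, e.drop_magnitude)
            for e in events]
    pd.DataFrame(rows, columns=["fov_id", "track_id", "event_frame", "x", "y",
                                "drop_sd"]).to_csv(path, index=False)


def write_dataset(path: str | Path, dataset: FluorescenceDataset) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path: str | Path) -> FluorescenceDataset:
    return FluorescenceDataset.from_frame(pd.read_csv(path))


def write_binding_curve(path: str | Path, curve: BindingCurve) -> None:
    pd.DataFrame({"concentration_M": curve.concentrations,
                  "response": curve.responses}).to_csv(path, index=False)


def read_binding_curve(path: str | Path) -> BindingCurve:
    df = pd.read_csv(path)
    return BindingCurve(df["concentration_M"].to_numpy(),
                        df["response"].to_numpy())


def write_ground_truth(path: str | Path, truth: TirfGroundTruth) -> None:
    payload = {
        "total_true_events": truth.total_true_events,
        "vesicles": [
            {
                "label": v.label,
                "event_frame": v.event_frame,
                "positions": np.asarray(v.positions).tolist(),
                "amplitudes": np.asarray(v.amplitudes).tolist(),
            }
            for v in truth.vesicles
        ],
    }
    write_json(path, payload)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
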
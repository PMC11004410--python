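"""Exocytosis (transcytosis) event calling and field-of-view counts.

A tracked vesicle is counted as an exocytosis event when it is
subdiffusive (alpha < 1, i.e. stationary / potentially docked), its
fluorescence falls by at least ``drop_sd`` standard deviations over the
last ``drop_window`` time points of its track, and no detection reappears
near its terminal position for ``disappearance_window`` subsequent frames.
Per-condition counts are background-corrected by subtracting the mean
count of no-ligand control movies acquired with identical settings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .detect import SpotDetection
from .track import Track

logger = logging.getLogger(__name__)

__all__ = [
    "EventParams",
    "ExocytosisEvent",
    "FovEventCount",
    "call_exocytosis_events",
    "correct_fov_counts",
]


@dataclass
class EventParams:
    drop_sd: float = 3.0              # required drop, in SDs of the track's earlier intensity
    drop_window: int = 5              # final time points over which the drop is measured
    disappearance_window: int = 5     # frames the vesicle must stay gone
    reappearance_radius: float = 2.0  # px; default 2 x linking displacement_scale
    sd_floor_fraction: float = 1e-9   # SD floor relative to the series scale


@dataclass
class ExocytosisEvent:
    track_id: int
    event_frame: int
    x: float
    y: float
    drop_magnitude: float  # drop in units of the baseline intensity SD


@dataclass
class FovEventCount:
    """Event count for one field of view, with background correction.

    ``corrected`` may be negative after subtracting the mean background
    count; it is reported as-is and only averaged across fields of view.
    """

    fov_id: str
    raw: int
    background_mean: float = 0.0
    n_nuclei: int | None = None

    @property
    def corrected(self) -> float:
        return self.raw - self.background_mean


def _intensity_drop(intensity: np.ndarray, params: EventParams) -> tuple[float, float]:
    """(drop, sd) of a track's intensity series.

    The SD population is the series excluding the last ``drop_window``
    points; the drop is the median of those earlier points minus the final
    value.  A floor keeps a constant noise-free series from dividing by
    zero.
    """
    earlier = intensity[:-params.drop_window]
    sd = float(np.std(earlier, ddof=1)) if len(earlier) > 1 else 0.0
    scale = max(float(np.max(np.abs(intensity))), 1.0)
    sd = max(sd, params.sd_floor_fraction * scale)
    drop = float(np.median(earlier)) - float(intensity[-1])
    return drop, sd


def call_exocytosis_events(tracks: list[Track],
                           detections_by_frame: list[list[SpotDetection]],
                           params: EventParams | None = None) -> list[ExocytosisEvent]:
    """Call at most one exocytosis event per eligible track.

    Eligibility: the track is subdiffusive, ends at least
    ``disappearance_window`` frames before the movie ends (otherwise the
    no-reappearance check cannot be evaluated — censored), its intensity
    drop is at least ``drop_sd`` SDs, and no detection lies within
    ``reappearance_radius`` of the terminal position in the
    ``disappearance_window`` frames after the track ends.  Tracks without a
    defined alpha are skipped and counted.
    """
    params = params or EventParams()
    n_frames = len(detections_by_frame)
    events: list[ExocytosisEvent] = []
    n_no_alpha = 0
    for tr in tracks:
        if tr.alpha is None:
            n_no_alpha += 1
            continue
        if not tr.is_subdiffusive:
            continue
        if tr.end_frame >= n_frames - params.disappearance_window:
            continue  # censored: the movie ends inside the disappearance window
        if len(tr) <= params.drop_window:
            continue
        intensity = tr.intensity_series
        drop, sd = _intensity_drop(intensity, params)
        if drop < params.drop_sd * sd:
            continue
        terminal = tr.terminal_position
        reappeared = False
        for f in range(tr.end_frame + 1,
                       min(tr.end_frame + 1 + params.disappearance_window, n_frames)):
            for d in detections_by_frame[f]:
                if np.hypot(d.x - terminal[0], d.y - terminal[1]) <= params.reappearance_radius:
                    reappeared = True
                    break
            if reappeared:
                break
        if reappeared:
            continue
        events.append(ExocytosisEvent(
            track_id=tr.track_id,
            event_frame=tr.end_frame,
            x=float(terminal[0]), y=float(terminal[1]),
            drop_magnitude=drop / sd,
        ))
    if n_no_alpha:
        logger.info("skipped %d tracks without a defined alpha", n_no_alpha)
    logger.info("called %d exocytosis events from %d tracks", len(events), len(tracks))
    return events


def correct_fov_counts(sample_counts: list[int],
                       background_counts: list[int]) -> tuple[list[float], float]:
    """Subtract the mean no-ligand background count from each field of view.

    Returns the per-field corrected counts (may be negative) and their
    mean.  An empty background list applies a correction of zero with a
    warning.
    """
    if len(background_counts) == 0:
        warnings.warn("no background movies supplied; correction of 0 applied",
                      stacklevel=2)
        bg_mean = 0.0
    else:
        bg_mean = float(np.mean(background_counts))
    corrected = [float(c) - bg_mean for c in sample_counts]
    mean = float(np.mean(corrected)) if corrected else 0.0
    return corrected, mean
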
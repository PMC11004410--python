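"""Frame-to-frame particle linking and diffusivity analysis.

Detections are linked by maximum likelihood under an isotropic Gaussian
model of centroid displacement and peak-intensity change: each frame pair
is solved as an optimal one-to-one assignment minimizing

    cost(link) = (dr / displacement_scale)^2 + (dI_peak / intensity_scale)^2

with links beyond ``max_displacement`` forbidden.  Per-track mean squared
displacement is time-averaged within the track and the anomalous exponent
alpha is the log-log slope over the first few lags; tracks with alpha < 1
are flagged subdiffusive (stationary / potentially docked), the population
from which exocytosis events may be called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import SpotDetection

logger = logging.getLogger(__name__)

__all__ = [
    "LinkParams",
    "Track",
    "link_tracks",
    "compute_msd",
    "fit_msd_exponent",
]

_FORBIDDEN = 1e12  # cost sentinel; any admissible assignment beats one forbidden link


@dataclass
class LinkParams:
    max_displacement: float = 4.0     # px per frame, gating radius
    displacement_scale: float = 1.0   # px
    intensity_scale: float = 20.0     # intensity units
    gap_max: int = 0                  # frames a track may skip while linking
    min_track_length: int = 10        # frames; >= the 5-point drop window

    def validate(self) -> None:
        if self.displacement_scale <= 0 or self.intensity_scale <= 0:
            raise ValueError("scales must be > 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


@dataclass
class Track:
    """A linked trajectory of detections.

    ``frames`` are strictly increasing (gaps allowed up to ``gap_max``).
    ``alpha`` is filled by :func:`fit_msd_exponent` via
    :meth:`compute_motion`; it is None when fewer than 3 usable MSD points
    exist, in which case the track is excluded from event calling.
    """

    track_id: int
    detections: list[SpotDetection] = field(default_factory=list)
    alpha: float | None = None
    msd: np.ndarray | None = None

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections])

    @property
    def intensity_series(self) -> np.ndarray:
        return np.array([d.peak_intensity for d in self.detections])

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame_index

    @property
    def terminal_position(self) -> np.ndarray:
        return self.detections[-1].position

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def is_subdiffusive(self) -> bool:
        return self.alpha is not None and self.alpha < 1.0

    def compute_motion(self, max_lag: int = 20, fit_lags: int = 5) -> None:
        """Fill ``msd`` and ``alpha`` for this track."""
        self.msd = compute_msd(self, max_lag)
        self.alpha = fit_msd_exponent(self.msd, fit_lags)


def link_cost(a: SpotDetection, b: SpotDetection, params: LinkParams) -> float:
    """Quadratic (Gaussian log-likelihood) cost of linking two detections."""
    dr = np.hypot(b.x - a.x, b.y - a.y)
    if dr > params.max_displacement:
        return _FORBIDDEN
    di = b.peak_intensity - a.peak_intensity
    return (dr / params.displacement_scale) ** 2 + (di / params.intensity_scale) ** 2


def link_tracks(detections_by_frame: list[list[SpotDetection]],
                params: LinkParams | None = None) -> list[Track]:
    """Link per-frame detections into tracks.

    Each consecutive frame pair is solved as a rectangular assignment
    problem; with the forbidden-link sentinel much larger than any
    admissible total, the optimum first maximizes the number of admissible
    links and then minimizes their summed cost.  Unmatched detections start
    new tracks.  Tracks shorter than ``min_track_length`` are dropped and
    each surviving track gets its MSD and alpha computed.
    """
    params = params or LinkParams()
    params.validate()
    open_tracks: list[Track] = []   # candidate tracks awaiting extension
    done: list[Track] = []
    next_id = 0

    for t, dets in enumerate(detections_by_frame):
        # retire tracks that can no longer be extended
        still_open = []
        for tr in open_tracks:
            if t - tr.end_frame > params.gap_max + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        candidates = [tr for tr in open_tracks
                      if t - tr.end_frame <= params.gap_max + 1]
        assigned = set()
        if candidates and dets:
            cost = np.array([[link_cost(tr.detections[-1], d, params)
                              for d in dets] for tr in candidates])
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _FORBIDDEN:
                    candidates[i].detections.append(dets[j])
                    assigned.add(j)
        for j, d in enumerate(dets):
            if j not in assigned:
                open_tracks.append(Track(next_id, [d]))
                next_id += 1

    done.extend(open_tracks)
    tracks = [tr for tr in done if len(tr) >= params.min_track_length]
    tracks.sort(key=lambda tr: (tr.start_frame, tr.track_id))
    for new_id, tr in enumerate(tracks):
        tr.track_id = new_id
        tr.compute_motion()
    logger.info("linked %d tracks (>= %d frames) from %d candidate segments",
                len(tracks), params.min_track_length, len(done))
    return tracks


def compute_msd(track: Track, max_lag: int = 20) -> np.ndarray:
    """Time-averaged mean squared displacement, lags 1..min(max_lag, L-1).

    msd[tau - 1] = mean over all frame pairs (t, t + tau) present in the
    track of |r(t + tau) - r(t)|^2, in px^2.  Frame gaps are respected: a
    lag contributes NaN if no pair at that lag exists.
    """
    if len(track) < 2:
        raise ValueError("track must have >= 2 detections")
    frames = track.frames
    pos = track.positions
    span = int(frames[-1] - frames[0])
    max_lag = min(max_lag, span)
    index = {int(f): i for i, f in enumerate(frames)}
    msd = np.full(max_lag, np.nan)
    for tau in range(1, max_lag + 1):
        sq = [np.sum((pos[index[f + tau]] - pos[index[f]]) ** 2)
              for f in index if f + tau in index]
        if sq:
            msd[tau - 1] = float(np.mean(sq))
    return msd


def fit_msd_exponent(msd: np.ndarray, fit_lags: int = 5,
                     eps: float = 1e-12) -> float | None:
    """Anomalous-diffusion exponent: log-log slope of MSD over early lags.

    Least-squares line of log msd(tau) vs log tau over lags 1..fit_lags;
    points with msd <= eps (numerically zero — a perfectly stationary
    trajectory) are excluded.  Returns None when fewer than 3 usable points
    remain, leaving alpha undefined.
    """
    msd = np.asarray(msd, dtype=float)[:fit_lags]
    lags = np.arange(1, len(msd) + 1)
    ok = np.isfinite(msd) & (msd > eps)
    if ok.sum() < 3:
        return None
    slope, _ = np.polyfit(np.log(lags[ok]), np.log(msd[ok]), 1)
    return float(slope)
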
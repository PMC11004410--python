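"""Non-movie quantifications.

Covers the fluorescence bookkeeping around the tracking pipeline: per-cell
integrated density across a z-stack with optional cell-volume
normalization, en-face aorta LDL deposition per marker-positive area,
pull-down band-ratio quantification, and dissociation-constant fitting of
equilibrium binding curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .core import ImageStack, RoiMask
from .simulate import BindingCurve

__all__ = [
    "CellMeasurement",
    "KdFit",
    "PulldownLane",
    "integrated_density_per_cell",
    "volume_normalize",
    "aorta_background_level",
    "aorta_deposition",
    "pulldown_binding_ratio",
    "fit_kd",
]


@dataclass
class CellMeasurement:
    """Integrated fluorescence of one cell across a z-stack.

    ``total`` is the sum of the raw integrated density within the ROI over
    all slices (no background subtraction at this step).  Volume
    normalization divides by roi_area x n_slices — the slice count, not a
    physical z-interval, mirroring how cell volume is computed in the
    assay; a physical-volume variant can be layered on via the calibration
    stored in the stack.
    """

    cell_id: str
    replicate_id: int
    group: str                      # blank | ctrl | cond
    total: float
    roi_area: int
    n_slices: int
    volume_normalized_density: float | None = None


def integrated_density_per_cell(stack: ImageStack, roi: RoiMask,
                                cell_id: str = "", replicate_id: int = 0,
                                group: str = "cond") -> CellMeasurement:
    """Sum of raw integrated density within the ROI across all z-slices."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.data.shape[1:]:
        raise ValueError("roi shape must match stack planes")
    if not roi.any():
        raise ValueError("empty roi")
    total = float(stack.data[:, roi].sum())
    return CellMeasurement(cell_id=cell_id, replicate_id=replicate_id,
                           group=group, total=total,
                           roi_area=int(roi.sum()), n_slices=stack.n_planes)


def volume_normalize(measurement: CellMeasurement) -> CellMeasurement:
    """Divide the total by the cell volume, roi_area x n_slices."""
    if measurement.roi_area <= 0 or measurement.n_slices <= 0:
        raise ValueError("roi_area and n_slices must be > 0")
    vnd = measurement.total / (measurement.roi_area * measurement.n_slices)
    return replace(measurement, volume_normalized_density=vnd)


def aorta_background_level(control_stack: ImageStack, k: float = 2.0) -> float:
    """Background threshold from a no-LDL control acquisition: mean + k SD."""
    data = control_stack.data
    return float(data.mean() + k * data.std())


def aorta_deposition(ldl_channel: ImageStack, marker_mask: RoiMask,
                     background_level: float) -> float:
    """LDL deposition normalized to the marker-positive (CD31+) area.

    Sums max(0, pixel - background_level) over all z-planes of the LDL
    channel and divides by the marker mask area in pixels.
    """
    marker_mask = np.asarray(marker_mask, dtype=bool)
    area = int(marker_mask.sum())
    if area == 0:
        raise ValueError("marker mask has zero area")
    above = np.clip(ldl_channel.data - background_level, 0.0, None)
    return float(above.sum()) / area


@dataclass
class PulldownLane:
    """Band intensities of one pull-down lane."""

    variant: str          # WT | Milano
    bound: float          # APOA1 captured on the beads
    srb1: float           # immobilized SR-B1-GFP band
    input: float          # APOA1 input lane

    @property
    def normalized(self) -> float:
        """(bound / srb1) / input — APOA1 capture corrected for the amount
        of immobilized receptor and of APOA1 added."""
        if self.srb1 <= 0 or self.input <= 0:
            raise ValueError("srb1 and input band intensities must be > 0")
        return (self.bound / self.srb1) / self.input


def pulldown_binding_ratio(lanes: list[PulldownLane],
                           variant: str = "Milano",
                           reference: str = "WT") -> float:
    """Capture of ``variant`` relative to ``reference`` on one blot.

    Each lane's bound-band intensity is divided by its SR-B1-GFP band and
    then by the matching input band; the variant's mean normalized value is
    divided by the reference's.
    """
    by = {variant: [], reference: []}
    for lane in lanes:
        if lane.variant in by:
            by[lane.variant].append(lane.normalized)
    if not by[variant] or not by[reference]:
        raise ValueError(f"need lanes for both {variant!r} and {reference!r}")
    return float(np.mean(by[variant]) / np.mean(by[reference]))


@dataclass
class KdFit:
    """Result of a single-site isotherm fit."""

    kd: float
    baseline: float
    amplitude: float
    kd_stderr: float
    residual_norm: float
    converged: bool
    message: str = ""


def _isotherm(c: np.ndarray, kd: float, baseline: float, amplitude: float) -> np.ndarray:
    return baseline + amplitude * c / (kd + c)


def fit_kd(curve: BindingCurve) -> KdFit:
    """Nonlinear least-squares fit of the single-site binding isotherm.

    response(c) = baseline + amplitude * c / (Kd + c), with a fixed Hill
    coefficient of 1 and ligand depletion neglected (the labeled target is
    at 50 nM against micromolar Kd, an error below 1%).  Initialization:
    baseline = min response, amplitude = response range, Kd = concentration
    nearest the half-range response.  A failed fit is returned flagged
    (``converged=False``) with the solver message, never silently replaced.
    """
    c = curve.concentrations
    r = curve.responses
    if len(c) < 4:
        raise ValueError("need >= 4 points to fit")
    r_range = float(r.max() - r.min())
    half = r.min() + 0.5 * r_range
    kd0 = float(c[np.argmin(np.abs(r - half))])
    p0 = [kd0, float(r.min()), r_range if r_range > 0 else 1.0]
    try:
        popt, pcov = curve_fit(
            _isotherm, c, r, p0=p0,
            bounds=([np.finfo(float).tiny, -np.inf, -np.inf],
                    [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except RuntimeError as exc:
        return KdFit(kd=float("nan"), baseline=float("nan"),
                     amplitude=float("nan"), kd_stderr=float("nan"),
                     residual_norm=float("nan"), converged=False,
                     message=str(exc))
    residuals = r - _isotherm(c, *popt)
    kd_stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return KdFit(kd=float(popt[0]), baseline=float(popt[1]),
                 amplitude=float(popt[2]), kd_stderr=kd_stderr,
                 residual_norm=float(np.linalg.norm(residuals)), converged=True)
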
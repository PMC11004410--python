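"""Synthetic ground-truth data generators.

Every generator here emulates one of the raw-data modalities the analysis
modules consume, with known ground truth attached:

* :func:`simulate_tirf_movie` — a TIRF time-lapse of sub-resolution
  vesicles (freely diffusing, docked, or docked-then-exocytosing) rendered
  as 2D Gaussians on a noisy background.
* :func:`simulate_cell_fluorescence` — per-cell integrated fluorescence for
  blank / control / condition groups across replicates, with lognormal
  within-replicate spread and replicate-to-replicate shifts.
* :func:`simulate_binding_curve` — a single-site equilibrium binding
  isotherm sampled on a serial-dilution concentration series.
* :func:`simulate_aorta_tile` — a two-channel tile: an endothelial-marker
  (CD31-like) mask channel and an LDL-deposit channel of planted spots.

All generators are deterministic given their seed: the same seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageStack
from .stats import FluorescenceDataset

__all__ = [
    "TirfSimConfig",
    "VesicleTruth",
    "TirfGroundTruth",
    "FluorSimConfig",
    "BindingCurve",
    "simulate_tirf_movie",
    "simulate_cell_fluorescence",
    "simulate_binding_curve",
    "simulate_aorta_tile",
    "add_noise",
    "render_gaussian_spot",
]

DIFFUSING = "diffusing"
DOCKED = "docked"
EXOCYTOSING = "exocytosing"


# ---------------------------------------------------------------------------
# TIRF movies
# ---------------------------------------------------------------------------

@dataclass
class TirfSimConfig:
    """Parameters of a simulated TIRF movie.

    Defaults reproduce the acquisition geometry of the assay this package
    quantifies: 150 frames at 100 ms exposure (a 15 s window).  Spatial
    calibration is a free knob; the default of 20 nm/px places thresholded
    spot masks inside the 60–200 nm equivalent-diameter acceptance band of
    the detector.
    """

    frame_count: int = 150
    frame_interval: float = 0.1          # seconds
    image_size: int = 96                 # pixels per side
    pixel_size: float = 20.0             # nm per pixel
    psf_sigma: float = 1.5               # pixels
    n_diffusing: int = 5
    n_docked: int = 5
    n_exocytosing: int = 5
    diffusion_coeff: float = 0.05        # px^2 / frame (MSD = 4 D tau)
    confinement_radius: float = 1.0      # px, docked-class jitter bound
    spot_amplitude: float = 200.0
    background_level: float = 100.0
    noise_sigma: float = 2.0
    event_frame_range: tuple[int, int] = (30, 120)
    event_residual_fraction: float = 0.25  # amplitude left on the fusion frame
    min_separation: float = 14.0         # px between initial positions
    edge_margin: float = 6.0             # px, trajectories reflected here
    seed: int = 0

    def validate(self) -> None:
        if self.frame_count < 10:
            raise ValueError("frame_count must be >= 10")
        if min(self.n_diffusing, self.n_docked, self.n_exocytosing) < 0:
            raise ValueError("vesicle counts must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.event_frame_range
        if lo < 5 or hi > self.frame_count - 6 or lo > hi:
            raise ValueError(
                "event_frame_range must leave >= 5 frames of track before the "
                "event and >= 5 frames after for the disappearance check"
            )


@dataclass
class VesicleTruth:
    """Ground truth for one simulated vesicle."""

    label: str                         # diffusing | docked | exocytosing
    positions: np.ndarray              # (frame_count, 2) sub-pixel (x, y)
    amplitudes: np.ndarray             # (frame_count,) emitted intensity
    event_frame: int | None = None     # fusion frame for the exocytosing class


@dataclass
class TirfGroundTruth:
    vesicles: list[VesicleTruth]
    config: TirfSimConfig

    @property
    def total_true_events(self) -> int:
        return sum(v.label == EXOCYTOSING for v in self.vesicles)


def _place_positions(rng: np.random.Generator, n: int, size: int,
                     margin: float, min_sep: float) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (dart throwing)."""
    out: list[np.ndarray] = []
    for _ in range(20000):
        if len(out) == n:
            break
        p = rng.uniform(margin, size - margin, 2)
        if all(np.hypot(*(p - q)) >= min_sep for q in out):
            out.append(p)
    if len(out) < n:
        raise ValueError(
            f"could not place {n} vesicles at separation {min_sep} in a "
            f"{size}x{size} field; reduce counts or min_separation"
        )
    return np.array(out).reshape(n, 2)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi]."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def render_gaussian_spot(frame: np.ndarray, x: float, y: float,
                         amplitude: float, sigma: float) -> None:
    """Add a 2D Gaussian of peak ``amplitude`` at sub-pixel (x, y), in place.

    Rendering is truncated at 4 sigma; the neglected mass is < 4e-4.
    """
    if amplitude <= 0:
        return
    h, w = frame.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(0, int(np.floor(x)) - r), min(w, int(np.floor(x)) + r + 1)
    y0, y1 = max(0, int(np.floor(y)) - r), min(h, int(np.floor(y)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma ** 2))
    frame[y0:y1, x0:x1] += amplitude * g


def simulate_tirf_movie(config: TirfSimConfig) -> tuple[ImageStack, TirfGroundTruth]:
    """Render a seeded TIRF movie and its per-vesicle ground truth.

    Vesicle classes:

    * *diffusing* — Brownian steps with per-axis variance ``2 D`` per frame,
      reflected at the field margins (MSD slope gives alpha ≈ 1).
    * *docked* — independent per-frame jitter about a fixed anchor, bounded
      by ``confinement_radius`` (MSD saturates immediately: alpha ≈ 0).
    * *exocytosing* — docked motion until ``event_frame``; on that frame the
      emitted amplitude falls to ``event_residual_fraction`` of its value
      and is zero afterwards (the drop completes within 2 frames and the
      vesicle never reappears).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, S = config.frame_count, config.image_size
    labels = ([DIFFUSING] * config.n_diffusing
              + [DOCKED] * config.n_docked
              + [EXOCYTOSING] * config.n_exocytosing)
    n = len(labels)
    starts = _place_positions(rng, n, S, config.edge_margin, config.min_separation)

    vesicles: list[VesicleTruth] = []
    for label, start in zip(labels, starts):
        if label == DIFFUSING:
            steps = rng.normal(0.0, np.sqrt(2 * config.diffusion_coeff), (T, 2))
            steps[0] = 0.0
            pos = start + np.cumsum(steps, axis=0)
            pos = _reflect(pos, config.edge_margin, S - config.edge_margin)
        else:
            jitter = rng.normal(0.0, config.confinement_radius / 2.0, (T, 2))
            jitter = np.clip(jitter, -config.confinement_radius,
                             config.confinement_radius)
            pos = start + jitter
        amp = np.full(T, config.spot_amplitude)
        event_frame = None
        if label == EXOCYTOSING:
            lo, hi = config.event_frame_range
            event_frame = int(rng.integers(lo, hi + 1))
            amp[event_frame] = config.event_residual_fraction * config.spot_amplitude
            amp[event_frame + 1:] = 0.0
        vesicles.append(VesicleTruth(label, pos, amp, event_frame))

    movie = np.full((T, S, S), config.background_level, dtype=np.float64)
    for t in range(T):
        for v in vesicles:
            render_gaussian_spot(movie[t], v.positions[t, 0], v.positions[t, 1],
                                 v.amplitudes[t], config.psf_sigma)
    if config.noise_sigma > 0:
        movie += rng.normal(0.0, config.noise_sigma, movie.shape)

    stack = ImageStack(movie.astype(np.float32),
                       pixel_size_nm=config.pixel_size,
                       frame_interval_s=config.frame_interval)
    return stack, TirfGroundTruth(vesicles, config)


def add_noise(stack: ImageStack, sigma: float, seed: int) -> ImageStack:
    """Return a copy of ``stack`` with seeded additive Gaussian noise.

    The noise field is generated once at unit variance and scaled by
    ``sigma``, so for a fixed seed a ladder of sigmas shares the same
    realization — useful when probing how detection degrades with noise.
    """
    rng = np.random.default_rng(seed)
    unit = rng.standard_normal(stack.data.shape).astype(np.float32)
    return ImageStack(stack.data + sigma * unit,
                      pixel_size_nm=stack.pixel_size_nm,
                      frame_interval_s=stack.frame_interval_s,
                      meta=dict(stack.meta))


# ---------------------------------------------------------------------------
# Per-cell fluorescence datasets
# ---------------------------------------------------------------------------

@dataclass
class FluorSimConfig:
    """Parameters of a simulated per-cell fluorescence experiment.

    Cells are drawn lognormally.  The decade-spanning 1e4–1e6 range of
    integrated per-cell fluorescence seen in primary endothelial cells is
    reproduced by two components: a between-replicate shift of the
    replicate's log-mean (``rep_log10_sd``, emulating passage-to-passage
    variability) and a moderate within-replicate spread
    (``ctrl_log10_sd``).  The within-replicate ratio statistic cancels the
    former by construction.  ``true_effect`` multiplies every condition
    cell; 1.0 is the null.
    """

    n_replicates: int = 6
    cells_per_group: int = 40
    blank_log10_mean: float = 3.0
    blank_log10_sd: float = 0.13
    ctrl_log10_mean: float = 5.0
    ctrl_log10_sd: float = 0.13
    rep_log10_sd: float = 0.35
    true_effect: float = 1.0
    condition_label: str = "cond"
    seed: int = 0

    def validate(self) -> None:
        if self.true_effect <= 0:
            raise ValueError("true_effect must be > 0")
        if self.cells_per_group <= 0:
            raise ValueError("cells_per_group must be > 0")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be > 0")


def simulate_cell_fluorescence(config: FluorSimConfig) -> FluorescenceDataset:
    """Simulate a per-cell fluorescence dataset.

    Condition cells are control-law draws multiplied by ``true_effect``;
    all values are strictly positive and each cell records its replicate.
    The returned dataset round-trips through a tidy table
    (``replicate_id, group, condition_label, value``) via ``to_frame``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ln10 = np.log(10.0)
    rows = []
    for k in range(config.n_replicates):
        shift = rng.normal(0.0, config.rep_log10_sd)
        blank = rng.lognormal((config.blank_log10_mean + shift) * ln10,
                              config.blank_log10_sd * ln10, config.cells_per_group)
        ctrl = rng.lognormal((config.ctrl_log10_mean + shift) * ln10,
                             config.ctrl_log10_sd * ln10, config.cells_per_group)
        cond = config.true_effect * rng.lognormal(
            (config.ctrl_log10_mean + shift) * ln10,
            config.ctrl_log10_sd * ln10, config.cells_per_group)
        for group, vals in (("blank", blank), ("ctrl", ctrl), ("cond", cond)):
            label = config.condition_label if group == "cond" else group
            rows.append(pd.DataFrame({
                "replicate_id": k,
                "group": group,
                "condition_label": label,
                "value": vals,
            }))
    return FluorescenceDataset.from_frame(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Binding curves
# ---------------------------------------------------------------------------

@dataclass
class BindingCurve:
    """A dose-response series for an equilibrium binding experiment.

    Concentrations are molar, strictly increasing; responses are in
    normalized fluorescence units.  ``target_concentration`` records the
    labeled-target concentration (50 nM in the thermophoresis assay) as
    metadata — at nanomolar target and micromolar Kd, ligand depletion is
    negligible and the simple hyperbolic isotherm applies.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    target_concentration: float = 50e-9

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.ndim != 1 or len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses must be 1D and equal length")
        if np.any(self.concentrations <= 0) or np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")


def simulate_binding_curve(kd: float, n_points: int = 16,
                           conc_range: tuple[float, float] = (1e-9, 8e-6),
                           noise_sd: float = 0.02, baseline: float = 0.0,
                           amplitude: float = 1.0, seed: int = 0) -> BindingCurve:
    """Sample a single-site isotherm on a geometric dilution series.

    response(c) = baseline + amplitude * c / (kd + c) + N(0, noise_sd * amplitude)

    ``kd`` and the concentration range are molar; ``noise_sd`` is a
    fraction of the amplitude.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    rng = np.random.default_rng(seed)
    conc = np.geomspace(conc_range[0], conc_range[1], n_points)
    resp = baseline + amplitude * conc / (kd + conc)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd * amplitude, n_points)
    return BindingCurve(conc, resp)


# ---------------------------------------------------------------------------
# Aorta deposition tiles
# ---------------------------------------------------------------------------

def simulate_aorta_tile(size: int = 128, background_level: float = 50.0,
                        n_ldl_spots: int = 30, spot_amplitude: float = 150.0,
                        marker_mask_fraction: float = 0.6,
                        spot_sigma: float = 2.0, noise_sigma: float = 0.0,
                        marker_level: float = 500.0,
                        seed: int = 0) -> tuple[ImageStack, float, np.ndarray]:
    """Simulate a two-channel en-face aorta tile.

    Channel 0 renders the endothelial-marker (CD31-like) area as a band of
    constant intensity; channel 1 is a uniform tissue background with
    ``n_ldl_spots`` Gaussian LDL deposits planted inside the marker area.

    Returns ``(stack, true_signal, marker_mask)`` where ``true_signal`` is
    the exact integrated above-background intensity planted in channel 1.
    """
    if not 0 < marker_mask_fraction <= 1:
        raise ValueError("marker_mask_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = max(1, int(round(marker_mask_fraction * size)))
    mask = np.zeros((size, size), dtype=bool)
    mask[:rows] = True

    signal = np.zeros((size, size))
    margin = 3 * spot_sigma
    for _ in range(n_ldl_spots):
        x = rng.uniform(margin, size - margin)
        y = rng.uniform(margin, rows - margin) if rows > 2 * margin else rng.uniform(0, rows)
        render_gaussian_spot(signal, x, y, spot_amplitude, spot_sigma)
    true_signal = float(signal.sum())

    marker = np.where(mask, marker_level, 0.0)
    ldl = background_level + signal
    data = np.stack([marker, ldl])
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, data.shape)
    return ImageStack(data.astype(np.float32)), true_signal, mask
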
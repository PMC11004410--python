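import numpy as np
import pytest

from transcyt import (DetectionParams, EventParams, LinkParams, TirfSimConfig,
                      call_exocytosis_events, detect_movie, link_tracks,
                      simulate_tirf_movie)


@pytest.fixture(scope="session")
def noise_free_movie():
    """One noise-free default movie with ground truth (shared: rendering and
    detection are the slow parts of the suite)."""
    config = TirfSimConfig(noise_sigma=0.0, seed=11)
    stack, truth = simulate_tirf_movie(config)
    return stack, truth


@pytest.fixture(scope="session")
def noise_free_pipeline(noise_free_movie):
    """Detections, tracks and called events for the shared movie."""
    stack, truth = noise_free_movie
    per_frame = detect_movie(stack, DetectionParams())
    tracks = link_tracks(per_frame, LinkParams())
    events = call_exocytosis_events(tracks, per_frame, EventParams())
    return per_frame, tracks, events, truth


def render_frame(size, spots, sigma=1.5):
    """Render Gaussian spots (x, y, amplitude) on a zero background."""
    from transcyt.simulate import render_gaussian_spot
    frame = np.zeros((size, size))
    for x, y, amp in spots:
        render_gaussian_spot(frame, x, y, amp, sigma)
    return frame
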
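"""Shared fixtures: simulated plates, rendered videos, tracked output.

Everything is generated programmatically with fixed seeds; the expensive
24-well rendered video and its tracking result are session-scoped so the
tracker unit tests and the fidelity checks share one computation.
"""

import pytest

import welltrack as wt


@pytest.fixture(scope="session")
def plate24():
    return wt.make_plate(24, radius=26.0)


@pytest.fixture(scope="session")
def truth500(plate24):
    """24 individuals, 500 frames, default population spread."""
    pop = wt.PopulationParams(n_individuals=24, seed=5)
    return wt.simulate_trajectories(pop, plate24, 500)


@pytest.fixture(scope="session")
def render500(plate24, truth500):
    """Rendered video at default appearance (noise + reflections on)."""
    return wt.render_video(truth500, plate24, wt.RenderConfig(seed=5))


@pytest.fixture(scope="session")
def tracked500(plate24, render500):
    return wt.track_video(render500.frames, plate24)


@pytest.fixture(scope="session")
def plate_image(render500):
    """First frame of the rendered plate as float image in [0, 1]."""
    return render500.frames[0].astype(float) / 255.0
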
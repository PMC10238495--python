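"""Shared synthetic fixtures for the test suite."""

import numpy as np
import pytest

from ridgemetrics import synthetic


@pytest.fixture(scope="session")
def stripes_scene():
    """Noisy stripe pattern at the paper-like pixel pitch and wavelength."""
    return synthetic.make_labyrinth(0.66, (128, 128), 0.098, "stripes",
                                    seed=11, noise=0.2)


@pytest.fixture(scope="session")
def labyrinth_scene():
    return synthetic.make_labyrinth(0.66, (128, 128), 0.098, "labyrinth",
                                    seed=7, noise=0.05)


@pytest.fixture(scope="session")
def cell_sheet():
    """5x5 jittered cell lattice: 9 interior cells, 16 border-clipped."""
    return synthetic.make_cell_sheet(n_x=5, n_y=5, cell_px=40, jitter=0.12,
                                     seed=3)


@pytest.fixture(scope="session")
def source_flow_scene():
    """Pure source field, divergence 2c = 0.2 min^-1 (above 0.12 threshold)."""
    return synthetic.make_flow_scene("source", 0.1, (96, 96), dt=0.5, seed=5)
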
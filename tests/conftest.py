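"""Shared fixtures: small-grid synthetic eyes, a normative atlas and a
processed healthy/glaucoma twin pair (expensive, session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

import octsp
import octsp.features as feat
import octsp.pipeline as pl
import octsp.superpixel as spx
from octsp.synthetic import sample_phenotype

GRID_N = 64


@pytest.fixture(scope="session")
def grid64():
    return octsp.GridSpec.for_size(GRID_N)


@pytest.fixture(scope="session")
def healthy_eye64(grid64):
    return octsp.generate_eye(
        octsp.EyePhenotype(bundle_angles=(65.0, 295.0)), grid64, rng_seed=3
    )


@pytest.fixture(scope="session")
def atlas64(grid64):
    rng = np.random.default_rng(11)
    eyes = [
        octsp.generate_eye(
            sample_phenotype("healthy", rng), grid64,
            rng_seed=int(rng.integers(2**31)),
        )
        for _ in range(12)
    ]
    return pl.build_normative_atlas_from_eyes(eyes)


@pytest.fixture(scope="session")
def params64():
    return spx.SegmentationParams.for_grid(GRID_N, seed=0)


@pytest.fixture(scope="session")
def thresholds64():
    return feat.SizeThresholds.for_grid(GRID_N)


def make_twin(grid, depth, seed=5, width=40.0, center=65.0, extent=2.8):
    """Paired eyes sharing seed/vessels, differing only in defect depth."""
    defects = (octsp.Defect(center, width, depth, extent),) if depth > 0 else ()
    ph = octsp.EyePhenotype(
        group="glaucoma" if depth > 0 else "healthy",
        bundle_angles=(65.0, 295.0),
        defects=defects,
        vessel_seed=seed,
    )
    return octsp.generate_eye(ph, grid, rng_seed=seed)


@pytest.fixture(scope="session")
def processed_pair64(grid64, atlas64, params64, thresholds64):
    """process_eye results for a healthy eye and its deep-defect twin."""
    healthy = make_twin(grid64, 0.0)
    glaucoma = make_twin(grid64, 0.9)
    return (
        pl.process_eye(healthy, atlas64, params64, thresholds64),
        pl.process_eye(glaucoma, atlas64, params64, thresholds64),
        healthy,
        glaucoma,
    )
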
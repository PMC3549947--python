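"""Shared phantom fixtures.

Expensive end-to-end runs are session-scoped so unit tests and acceptance
tests reuse the same computation.
"""
import warnings

import numpy as np
import pytest

from canaliz import io_cli, phantom


@pytest.fixture(scope="session")
def straight_mct():
    """Straight-canal micro-CT phantom: radius 4 voxels, 200 slices."""
    spec = phantom.preset("straight", shape=(200, 64, 64), canal_radius=4.0)
    vol, truth = phantom.render_microct_stack(spec, shape=(200, 64, 64), seed=11)
    return spec, vol, truth


@pytest.fixture(scope="session")
def straight_mct_run(straight_mct):
    """Full micro-CT pipeline run on the straight phantom."""
    _, vol, truth = straight_mct
    cfg = io_cli.PipelineConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report, skel, result = io_cli.run_mct(cfg, stack=list(vol.voxels))
    return report, skel, result, truth


@pytest.fixture(scope="session")
def y_mct():
    """Y-bifurcation micro-CT phantom."""
    spec = phantom.preset("y-bifurcation", shape=(120, 64, 64), canal_radius=4.0)
    vol, truth = phantom.render_microct_stack(spec, shape=(120, 64, 64), seed=11)
    return spec, vol, truth


@pytest.fixture(scope="session")
def y_cbct():
    """Y-bifurcation CBCT phantom (canal a few voxels wide)."""
    spec = phantom.preset("y-bifurcation", shape=(64, 48, 48), canal_radius=3.0,
                          span="interior")
    vol, truth = phantom.render_cbct_volume(spec, shape=(64, 48, 48), seed=11)
    return spec, vol, truth


@pytest.fixture(scope="session")
def incisor_cbct():
    """Straight-canal ("incisor") CBCT phantom."""
    spec = phantom.preset("straight", shape=(64, 48, 48), canal_radius=2.0,
                          span="interior")
    vol, truth = phantom.render_cbct_volume(spec, shape=(64, 48, 48), seed=11)
    return spec, vol, truth


@pytest.fixture(scope="session")
def incisor_cbct_run(incisor_cbct):
    _, vol, truth = incisor_cbct
    cfg = io_cli.PipelineConfig(modality="cbct")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report, skel, tooth, canals = io_cli.run_cbct(cfg, (34, 24, 20),
                                                      volume=vol.voxels)
    return report, skel, tooth, canals, truth


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
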
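import numpy as np
import pytest

import voromorph as vm
from voromorph.synthetic import CapsuleParams, RenderParams


@pytest.fixture(scope="session")
def capsule_seeds() -> vm.SeedSet:
    """The bundled 22 labelled pore-centre coordinates."""
    return vm.datasets.capsule_seed_points()


@pytest.fixture(scope="session")
def capsule_tess(capsule_seeds) -> vm.Tessellation:
    return vm.build_voronoi(capsule_seeds)


@pytest.fixture(scope="session")
def default_params() -> CapsuleParams:
    return CapsuleParams()


@pytest.fixture(scope="session")
def horizontal_sample(default_params):
    """Horizontal capsule section at study-default parameters, fixed seed."""
    sites = vm.sample_pore_centers(default_params, (1600.0, 1600.0), rng_seed=11)
    return vm.render_capsule_cross_section(
        sites, default_params, RenderParams(rng_seed=12), orientation="horizontal"
    )


def segment_default(image, smoothing=1.0):
    """The default segmentation chain used by recovery tests: smooth + Otsu."""
    return vm.binarize(vm.preprocess(image, edge_emphasis=False, smoothing_scale=smoothing))
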
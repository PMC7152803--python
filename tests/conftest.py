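import warnings

import numpy as np
import pytest

from strokeangio.angiogram import average_series, quality_filter
from strokeangio.synthgen import (
    SceneSpec,
    StallProcessSpec,
    generate_scene,
    render_angiogram_series,
)

warnings.filterwarnings("ignore", message=".*empty.*")


@pytest.fixture(scope="session")
def lesion_scene():
    """128x128 scene with a 16 px lesion, default (uniform) orientations."""
    spec = SceneSpec.small(seed=101, lesion_radius_px=16)
    scene, truth = generate_scene(spec)
    return spec, scene, truth


@pytest.fixture(scope="session")
def quiet_series(lesion_scene):
    """Stall-free 60-frame series over the lesion scene."""
    spec, scene, truth = lesion_scene
    return render_angiogram_series(
        scene, truth, StallProcessSpec(stall_prob=0.0, seed=7), spec
    )


@pytest.fixture(scope="session")
def mean_enface(quiet_series):
    return average_series(quality_filter(quiet_series))


def pipeline_aligned_fraction(seed, align_fraction, lesion_radius_px=16,
                              n_bins=18):
    """Generator -> angiogram -> vesselness -> mask -> theta histogram."""
    from strokeangio.orientation import angular_distribution, compute_orientation_maps
    from strokeangio.vessels import frangi, make_mask

    spec = SceneSpec.small(seed=seed, lesion_radius_px=lesion_radius_px,
                           align_fraction=align_fraction)
    scene, truth = generate_scene(spec)
    series = render_angiogram_series(
        scene, truth, StallProcessSpec(stall_prob=0.0, seed=1), spec)
    mean = average_series(quality_filter(series))
    vness = frangi(mean)
    vmask = make_mask(vness)
    maps = compute_orientation_maps(vness, spec.center_xy)
    dist = angular_distribution(maps.theta, vmask, maps.coherence, n_bins=n_bins)
    return dist, maps, vmask, scene, truth


def rng_for(*parts):
    return np.random.default_rng(list(parts))
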
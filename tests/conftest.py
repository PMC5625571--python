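import numpy as np
import pytest

from hullcarve import CameraView, CarveConfig
from hullcarve import engine, scenes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170928)


@pytest.fixture(scope="session")
def sphere_scene():
    """Small sphere scene with 8 views; shared by several strategy tests."""
    shape = scenes.Sphere((0.0, 0.0, 0.0), 0.08)
    rig = scenes.make_rig(
        n_cameras=2, n_angles=4, focal_px=300, width=200, height=200,
        camera_distance=0.8, elevations_deg=[10.0, 40.0], target=(0.0, 0.0, 0.0),
    )
    views = [CameraView(m, P) for m, P in scenes.render_views(shape, rig)]
    config = CarveConfig(root_center=(0.0, 0.0, 0.0), root_edge=0.4, max_depth=5)
    return shape, views, config


@pytest.fixture(scope="session")
def toy_plant_scene():
    """The default toy-plant scene on the 9-view screening rig."""
    shape = scenes.toy_plant()
    rig = scenes.phenotyping_rig(
        focal_px=1400, width=320, height=320, camera_distance=0.9,
        target=(0.0, 0.0, 0.05),
    )
    views = [CameraView(m, P) for m, P in scenes.render_views(shape, rig)]
    config = CarveConfig(root_center=(0.0, 0.0, 0.05), root_edge=0.32, max_depth=7)
    return shape, rig, views, config


def random_scene(rng, n_views=None, depth=None, image=160):
    """A randomized small scene (shapes, views, config) for equivalence sweeps."""
    n_shapes = rng.integers(1, 4)
    shapes = []
    for _ in range(n_shapes):
        if rng.random() < 0.6:
            shapes.append(
                scenes.Sphere(rng.uniform(-0.05, 0.05, 3) + [0, 0, 0.05], rng.uniform(0.01, 0.04))
            )
        else:
            shapes.append(
                scenes.VerticalCylinder(
                    rng.uniform(-0.04, 0.04, 3) * [1, 1, 0.5],
                    rng.uniform(0.005, 0.02),
                    rng.uniform(0.03, 0.1),
                )
            )
    shape = scenes.ShapeUnion(tuple(shapes))
    n_views = int(rng.integers(4, 7)) if n_views is None else n_views
    depth = int(rng.integers(4, 7)) if depth is None else depth
    rig = scenes.make_rig(
        n_cameras=1, n_angles=n_views, focal_px=float(rng.uniform(250, 450)),
        width=image, height=image, camera_distance=float(rng.uniform(0.7, 1.1)),
        elevations_deg=[float(rng.uniform(5, 50))], target=(0.0, 0.0, 0.04),
    )
    views = [CameraView(m, P) for m, P in scenes.render_views(shape, rig)]
    config = CarveConfig(root_center=(0.0, 0.0, 0.04), root_edge=0.24, max_depth=depth)
    return shape, views, config


def carve_all_strategies(views, config):
    out = {}
    for s in engine.STRATEGIES:
        cfg = CarveConfig(
            root_center=config.root_center, root_edge=config.root_edge,
            max_depth=config.max_depth, strategy=s,
            outside_is_background=config.outside_is_background,
        )
        out[s] = engine.carve(views, cfg)
    return out
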
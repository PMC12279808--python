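import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 160px scene with two plants."""
    from gmacorn.scenes import SceneConfig, generate_scene
    cfg = SceneConfig(image_size=160, n_plants=2, whorl_radius=(8, 12))
    img, labels = generate_scene(cfg, seed=3)
    return cfg, img, labels


@pytest.fixture(scope="session")
def smoke_dataset():
    """16 synthetic 160x160 scenes for smoke training."""
    from gmacorn.scenes import SceneConfig, generate_scene
    cfg = SceneConfig(image_size=160, n_plants=2, whorl_radius=(8, 12))
    return [generate_scene(cfg, seed=s) for s in range(16)]


def tiny_gma(seed=0, aux=False):
    from gmacorn.arch import ArchConfig, build_model
    return build_model(ArchConfig(variant="gma", width=0.25,
                                  include_aux_head=aux, init_seed=seed))


def toy_grid(n=8, stride=8.0):
    xs = (np.arange(n) + 0.5) * stride
    px, py = np.meshgrid(xs, xs, indexing="xy")
    return np.stack([px.ravel(), py.ravel()], axis=1)


def toy_scene(rng, n=8, stride=8.0, n_gt=1):
    """Random toy anchors/predictions/ground truth for assigner tests."""
    pts = toy_grid(n, stride)
    a = len(pts)
    scores = rng.uniform(0.1, 0.9, size=(a, 1))
    jit = rng.uniform(-2, 2, size=(a, 2))
    half = rng.uniform(6, 14, size=(a, 1))
    boxes = np.concatenate([pts + jit - half, pts + jit + half], axis=1)
    lo, hi = stride, (n - 1) * stride
    gts = []
    for _ in range(n_gt):
        cx, cy = rng.uniform(lo, hi, size=2)
        w, h = rng.uniform(10, 25, size=2)
        gts.append([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])
    return scores, boxes, pts, np.array(gts), np.zeros(n_gt, dtype=int)
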
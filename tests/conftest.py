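import numpy as np
import pytest

from wildtrap import nn
from wildtrap.model_core import ModelConfig, build_model
from wildtrap.synthetic_data import SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """Very small detector for fast forward/backward tests."""
    return ModelConfig.baseline(width_multiple=0.125, input_size=64)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SceneConfig(image_size=96, seed=11), 6)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of scalar-valued f() w.r.t. array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def assert_grad_matches(make_out, tensors, tol=2e-2, probe_rng=None):
    """Backprop vs numerical gradient on a random-weighted output sum."""
    probe_rng = probe_rng or np.random.default_rng(123)
    probe = nn.Tensor(probe_rng.normal(size=make_out().shape).astype(np.float32))
    out = (make_out() * probe).sum()
    out.backward()
    for t in tensors:
        got = t.grad.copy()
        t.grad = None
        want = numerical_gradient(lambda: float((make_out() * probe).sum().data), t.data)
        scale = max(np.abs(want).max(), 1e-6)
        np.testing.assert_allclose(got, want, atol=tol * scale, rtol=tol)
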
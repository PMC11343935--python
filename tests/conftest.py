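import numpy as np
import pytest

from stresscast.synthetic_data import GeneratorSpec, generate_dataset


def logistic_orbit(n: int, seed: int = 0, r: float = 4.0) -> np.ndarray:
    """Reference logistic-map orbit (100-step transient discarded)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.1, 0.9)
    for _ in range(100):
        x = r * x * (1 - x)
    out = np.empty(n)
    for i in range(n):
        out[i] = x
        x = r * x * (1 - x)
    return out


def henon_orbit(n: int, seed: int = 0, a: float = 1.4, b: float = 0.3) -> np.ndarray:
    """x-coordinate of a Hénon orbit (100-step transient discarded)."""
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(-0.1, 0.1, size=2)
    for _ in range(100):
        x, y = 1 - a * x * x + y, b * x
    out = np.empty(n)
    for i in range(n):
        out[i] = x
        x, y = 1 - a * x * x + y, b * x
    return out


def henon_lyapunov_qr(n: int, seed: int = 0, a: float = 1.4, b: float = 0.3) -> float:
    """Independent oracle: largest Lyapunov exponent by Jacobian-product QR."""
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(-0.1, 0.1, size=2)
    for _ in range(100):
        x, y = 1 - a * x * x + y, b * x
    Q = np.eye(2)
    acc = 0.0
    for _ in range(n):
        J = np.array([[-2 * a * x, 1.0], [b, 0.0]])
        Q, R = np.linalg.qr(J @ Q)
        acc += np.log(abs(R[0, 0]))
        x, y = 1 - a * x * x + y, b * x
    return acc / n


@pytest.fixture(scope="session")
def logistic_5000():
    return logistic_orbit(5000, seed=1)


@pytest.fixture(scope="session")
def henon_5000():
    return henon_orbit(5000, seed=1)


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic stress benchmark: 50 users x 56 days."""
    return generate_dataset(GeneratorSpec())
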
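import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import planktonts as pts

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def campaign():
    """Default 8-year campaign at full noise, seed 1."""
    return pts.simulate_campaign(seed=1)


@pytest.fixture(scope="session")
def quiet_campaign():
    """8-year campaign in the noise-reduced recovery regime (seed 11)."""
    cfg = pts.default_config(seed=11).scale_noise(0.0)
    return pts.simulate_campaign(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_bray_curtis(x, y):
    """Elementwise reference Bray-Curtis, independent of the library path."""
    num = 0.0
    den = 0.0
    for xi, yi in zip(x, y):
        num += abs(xi - yi)
        den += xi + yi
    return num / den


def brute_force_spearman(x, y):
    """Reference Spearman: mid-ranks by explicit tie averaging, then the
    Pearson formula written out."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx = midranks(list(x))
    ry = midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
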
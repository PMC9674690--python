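import numpy as np
import pytest

from t1phasor import (
    MOLLI_TIMES,
    PhantomSpec,
    build_projection_plane,
    ir_to_decay,
    simulate_phantom,
)

ANCHORS = (1.5, 1.75, 2.0)


@pytest.fixture(scope="session")
def molli_times():
    """The 8 MOLLI inversion times (seconds) used by the phantom study."""
    return MOLLI_TIMES.copy()


@pytest.fixture(scope="session")
def ir_plane(molli_times):
    """Projection plane for converted IR data with the standard anchors."""
    return build_projection_plane(molli_times, ANCHORS, mode="inversion_recovery")


@pytest.fixture(scope="session")
def phantom_noiseless():
    """Noiseless default phantom: (fractions, raw IR stack, converted stack)."""
    fractions, stack = simulate_phantom(PhantomSpec())
    return fractions, stack, ir_to_decay(stack)


def naive_phasor(values):
    """Independent double-loop trigonometric-sum phasor oracle."""
    values = np.asarray(values, dtype=float)
    m = len(values)
    total = values.sum()
    g, s = [], []
    for n in range(1, m // 2 + 1):
        cg = cs = 0.0
        for k in range(m):
            cg += values[k] * np.cos(2 * np.pi * n * k / m)
            cs += values[k] * np.sin(2 * np.pi * n * k / m)
        g.append(cg / total)
        s.append(cs / total)
    return np.array(g), np.array(s)
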
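import numpy as np
import pytest


def simpson_arc_length(L: float, W: float, n: int = 10_000) -> float:
    """Independent composite-Simpson oracle for the one-sided arc length.

    Integrates sqrt(1 + 9 L^2 / W^6 x^4) over [0, W] on n (even) subintervals
    without using the package's quadrature path.
    """
    x = np.linspace(0.0, W, n + 1)
    y = np.sqrt(1.0 + 9.0 * L * L / W**6 * x**4)
    h = W / n
    return h / 3.0 * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-1:2].sum())


@pytest.fixture(scope="session")
def simpson_oracle():
    return simpson_arc_length
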
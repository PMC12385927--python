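import math

import numpy as np
import pytest

from hdmorph.geometry import Contour, LayerDelineation

#: Aganglionic per-layer cohort means (mm), lumen-outward order.
AGANGLIONIC_MEANS = {
    "mucosa": 0.505,
    "submucosa": 0.618,
    "muscularis_interna": 0.461,
    "myenteric": 0.018,
    "muscularis_externa": 0.401,
}


def circle(radius_um: float, n: int = 4096, center=(0.0, 0.0), closed: bool = True,
           span=(0.0, 2.0 * math.pi), label: str = "") -> Contour:
    theta = np.linspace(span[0], span[1], n, endpoint=not closed)
    pts = np.column_stack(
        [center[0] + radius_um * np.cos(theta), center[1] + radius_um * np.sin(theta)]
    )
    return Contour(pts, closed=closed, label=label)


@pytest.fixture
def annulus():
    """Concentric circles r=1000/1500 µm: thickness 0.5 mm everywhere."""
    return LayerDelineation("submucosa", circle(1000.0), circle(1500.0))


def star_convex_contour(rng: np.random.Generator, base_radius_um: float = 300.0,
                        amplitude: float = 0.15, n: int = 2048) -> Contour:
    """Random smooth star-convex closed contour (low-order harmonics)."""
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r = np.full_like(theta, base_radius_um)
    for m in range(2, 7):
        r = r + base_radius_um * amplitude / m * np.cos(m * theta + rng.uniform(0, 2 * math.pi))
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]), closed=True)
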
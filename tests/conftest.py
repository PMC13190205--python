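import numpy as np
import pytest

from pgk.encoding import TRAIT_CODES, PerceptualTraitVector, RawTraitRecord

# Reference perceptual intensities for a healthy and a severely
# stressed plant, in canonical trait order (LC, LA, TU, VP, ES, WI).
HEALTHY = (0.92, 0.88, 0.90, 0.85, 0.87, 0.12)
STRESS = (0.45, 0.41, 0.39, 0.72, 0.36, 0.91)


@pytest.fixture
def healthy_vector() -> PerceptualTraitVector:
    return PerceptualTraitVector(owner_id="healthy", intensities=np.array(HEALTHY))


@pytest.fixture
def stress_vector() -> PerceptualTraitVector:
    return PerceptualTraitVector(owner_id="stress", intensities=np.array(STRESS))


def make_record(plant_id="p1", zone_id="z1", acre_id="a1", values=None, condition=None):
    if values is None:
        values = {c: float(i + 1) for i, c in enumerate(TRAIT_CODES)}
    return RawTraitRecord(
        plant_id=plant_id,
        zone_id=zone_id,
        acre_id=acre_id,
        values=values,
        condition=condition,
    )


def random_graphs(n, seed=0, epsilon_choices=(0.0, 0.05, 0.1, 0.3)):
    """Random deviation graphs over the canonical trait set."""
    from pgk.graphs import build_deviation_graph

    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n):
        vec = PerceptualTraitVector(owner_id=f"g{i}", intensities=rng.uniform(0, 1, 6))
        eps = float(rng.choice(epsilon_choices))
        graphs.append(build_deviation_graph(vec, epsilon=eps))
    return graphs
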
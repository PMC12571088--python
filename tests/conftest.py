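"""Shared fixtures: small synthetic bundles kept cheap enough to reuse.

Specimen counts are scaled down from the full study conditions so the
whole suite runs quickly; tests that probe the statistical structure use
species-mean bundles (no within-species noise), which is the level the
main analyses operate at anyway.
"""

import numpy as np
import pytest

from morphx.shape_core import superimpose
from morphx.synthetic import GeneratorConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """30 species with 2-4 teeth each (upper and lower jaws)."""
    cfg = GeneratorConfig(teeth_per_species=(2, 4))
    return generate_bundle(cfg, seed=11)


@pytest.fixture(scope="session")
def species_bundle():
    """One noise-free mean configuration per species."""
    return generate_bundle(GeneratorConfig(), seed=7, include_specimens=False)


@pytest.fixture(scope="session")
def aligned_species(species_bundle):
    return superimpose(species_bundle.configurations, slide=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_configs(rng, n=3, p=10):
    """Unstructured landmark configurations (no curves) for GPA tests."""
    from morphx.io_formats import LandmarkConfiguration, ROLE_FIXED

    out = []
    for i in range(n):
        out.append(
            LandmarkConfiguration(
                specimen_id=f"s{i}__upper__1__right__{i:03d}",
                species_id=f"s{i}",
                points=rng.normal(size=(p, 2)),
                roles=np.array([ROLE_FIXED] * p, dtype=object),
                curves=[],
            )
        )
    return out
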
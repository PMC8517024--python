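import numpy as np
import pytest

from cellmech.model_builder import (BeadConfiguration, GeometryConfig,
                                    InteractionTable, build_cell,
                                    default_pair_rules)


@pytest.fixture(scope="session")
def default_cell():
    """The full 201-membrane-bead cell with default interactions."""
    return build_cell()


@pytest.fixture(scope="session")
def compact_geometry():
    return GeometryConfig.compact()


@pytest.fixture(scope="session")
def compact_cell(compact_geometry):
    return build_cell(compact_geometry)


def random_small_system(rng, n_min=4, n_max=12, min_separation=0.8):
    """A chain of <= 12 beads with FENE bonds, bends, and mixed pair rules;
    all separations kept away from singular regions."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        pos = rng.uniform(0, 1.2 * n ** 0.5, (n, 2))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        d[np.diag_indices(n)] = np.inf
        if d.min() > min_separation:
            break
    types = rng.choice([0, 1, 3], n)
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    r0 = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
    angles = np.column_stack([np.arange(n - 2), np.arange(1, n - 1),
                              np.arange(2, n)])
    table = InteractionTable(
        bonds, np.zeros(len(bonds), int), rng.uniform(2, 20, len(bonds)),
        r0, 0.6 * r0, angles, rng.uniform(0.5, 5, len(angles)),
        rng.uniform(1.2, np.pi, len(angles)),
        default_pair_rules(eps00=rng.uniform(0.2, 2),
                           eps03=rng.uniform(0.2, 2),
                           sigma_filament=1.0),
    )
    beads = BeadConfiguration(pos, np.zeros_like(pos), types,
                              np.zeros(n, int))
    return beads, table
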
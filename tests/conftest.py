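import numpy as np
import pytest

from polyrank.synthetic import simulate_genotypes, simulate_landscape, simulate_leaves


@pytest.fixture(scope="session")
def small_genotypes():
    """3 diploid taxa + 1 allotetraploid + 1 autotetraploid, modest size."""
    g, truth = simulate_genotypes(
        n_taxa=3,
        samples_per_taxon=4,
        n_sites=400,
        divergence_F=0.2,
        polyploid_specs={"allo": ("taxon00", "taxon01"), "auto": "auto:taxon02"},
        missing_rate=0.05,
        seed=12345,
    )
    return g, truth


@pytest.fixture(scope="session")
def sympatric_landscape():
    return simulate_landscape(
        grid_shape=(24, 36), n_env=3, n_occ_per_taxon=25,
        scenario="sympatric", seed=7,
    )


@pytest.fixture(scope="session")
def straight_leaves():
    annots, masks, truth = simulate_leaves(
        n_per_taxon=4, bend_curvature=0.0, dissection_amplitude=0.15, seed=3
    )
    return annots, masks, truth


def circle_polygon(n=4096, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])
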
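import numpy as np
import pandas as pd
import pytest

from pollenlra import (
    ErvDataset,
    KernelParams,
    RingVegetation,
    ScenarioConfig,
    generate_scenario,
)


@pytest.fixture
def kernel():
    """Reference plume kernel: v_g = 0.035 m/s, neutral atmosphere."""
    return KernelParams(fall_speed=0.035)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced landscape (8 sites, 600-m surveys) for fast unit tests."""
    cfg = ScenarioConfig(
        seed=42,
        n_sites=8,
        n_subregion_a=4,
        extent=600.0,
        counts_per_sample=1000,
    )
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def full_scale_scenario():
    """Default study conditions: 36 sites, 10 taxa, 1,000 grains/site."""
    return generate_scenario(ScenarioConfig(seed=7))


def toy_dataset(n_sites=4, counts_from_dwpa=False, seed=0, total=5000):
    """Tiny 3-taxon dataset with hand-set ring covers.

    With ``counts_from_dwpa`` the pollen proportions equal the normalised
    DWPA at the survey extent, so the ERV model fits exactly with unit
    productivities and no background.
    """
    rng = np.random.default_rng(seed)
    taxa = ["A", "B", "C"]
    kernels = {
        "A": KernelParams(0.02),
        "B": KernelParams(0.035),
        "C": KernelParams(0.05),
    }
    bounds = np.array([0.5, 50.0, 200.0, 500.0])
    veg = {}
    for k in range(n_sites):
        cover = pd.DataFrame(
            rng.uniform(0.05, 0.6, size=(3, 3)), index=taxa, columns=range(3)
        )
        veg[f"s{k}"] = RingVegetation(f"s{k}", bounds, cover)
    if counts_from_dwpa:
        from pollenlra import distance_weighted_abundance

        rows = {}
        for s, rv in veg.items():
            x = distance_weighted_abundance(rv, kernels, 500.0)
            rows[s] = np.round(total * x / x.sum()).astype(int)
        pollen = pd.DataFrame(rows).T[taxa]
    else:
        pollen = pd.DataFrame(
            rng.multinomial(total, [0.5, 0.3, 0.2], size=n_sites),
            index=[f"s{k}" for k in range(n_sites)],
            columns=taxa,
        )
    return ErvDataset(pollen, veg, kernels, reference_taxon="A")
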
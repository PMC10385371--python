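import numpy as np
import pytest

from reactscreen import potency_sar, synthetic_data


@pytest.fixture(scope="session")
def noisy_assay_fits():
    """500 seeded 4PL refits of noisy synthetic assays (2% multiplicative
    noise, planted IC50 = 0.2 µM, 3 replicates).  Shared by the recovery
    and standard-error-coverage checks so the suite is fit only once."""
    results = []
    for k in range(500):
        table, truth = synthetic_data.gen_assay(
            seed=20_000 + k, ic50=0.2, hill=1.0, noise=0.02, replicates=3
        )
        fit = potency_sar.fit_ic50(table, "synthetic")
        results.append((fit, truth))
    return results


@pytest.fixture()
def water_geometry():
    """A bent 3-atom molecule with partial charges (water-like)."""
    from reactscreen.io_formats import AtomRecord, MolecularGeometry

    atoms = [
        AtomRecord(1, "O", np.array([0.0, 0.0, 0.0]), partial_charge=-0.8),
        AtomRecord(2, "H", np.array([0.96, 0.0, 0.0]), partial_charge=0.4),
        AtomRecord(3, "H", np.array([-0.24, 0.93, 0.0]), partial_charge=0.4),
    ]
    return MolecularGeometry("water", atoms)
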
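import numpy as np
import pytest

from renoct import default_phenotypes, generate_dataset, render_bscan


@pytest.fixture(scope="session")
def phenotypes():
    return default_phenotypes()


@pytest.fixture(scope="session")
def cortex_scan(phenotypes):
    """One speckled cortex B-scan at full geometry."""
    return render_bscan(phenotypes["cortex"], seed=11)


@pytest.fixture(scope="session")
def pelvis_scan(phenotypes):
    """Zero-signal pelvis B-scan: only the lens-surface band is lit."""
    return render_bscan(phenotypes["pelvis"], noise_floor=0.0, seed=12)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-geometry dataset for structural (non-attenuation) checks."""
    return generate_dataset(
        n_subjects=3, n_per_class_per_subject=4, seed=5, shape=(120, 80)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
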
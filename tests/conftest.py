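import numpy as np
import pytest

from ruecanopy.spectra import SpectralRecord, SpectralSet
from ruecanopy.synthetic import TrialConfig, simulate_trial

NOISE_FREE = {"reflectance_sd": 0.0, "biomass_cv": 0.0, "li_sd": 0.0}


@pytest.fixture(scope="session")
def noise_free_trial():
    """Deterministic 11x3 trial with all noise terms off."""
    return simulate_trial(TrialConfig(noise=dict(NOISE_FREE), seed=3))


@pytest.fixture(scope="session")
def default_trial():
    """Deterministic 11x3 trial at the default noise levels."""
    return simulate_trial(TrialConfig(seed=7))


def make_record(reflectance, wavelengths=None, **meta):
    wavelengths = np.arange(350.0, 2501.0) if wavelengths is None else np.asarray(wavelengths, float)
    refl = np.broadcast_to(np.asarray(reflectance, float), wavelengths.shape).copy()
    meta.setdefault("plot_id", "p1")
    return SpectralRecord(wavelengths=wavelengths, reflectance=refl, **meta)


@pytest.fixture
def flat_record():
    """Full 1 nm grid at constant reflectance 0.5."""
    return make_record(0.5)


@pytest.fixture
def random_set():
    """Six random smooth spectra on the full grid."""
    rng = np.random.default_rng(42)
    grid = np.arange(350.0, 2501.0)
    recs = []
    for i in range(6):
        base = 0.2 + 0.1 * np.sin(grid / (150 + 10 * i)) + 0.05 * rng.standard_normal()
        recs.append(
            SpectralRecord(
                wavelengths=grid,
                reflectance=np.clip(base, 0.01, 0.99),
                plot_id=f"p{i % 3}",
                layer="canopy",
                stage_tag=f"s{i % 2}",
            )
        )
    return SpectralSet(recs)
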
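import numpy as np
import pytest

from methdep import ChromosomeTrack, MaternSpec
from methdep.synthetic_cohort import CohortSimConfig, simulate_positions, simulate_track


def make_track(
    n_sites: int,
    range_bp: float = 3000.0,
    sigma: float = 1.0,
    sigma0: float = 0.5,
    seed: int = 0,
    sample_id: str = "s",
    chromosome: int = 1,
) -> ChromosomeTrack:
    """Simulated residual track at clustered positions (shared helper)."""
    cfg = CohortSimConfig(sites_per_chromosome=n_sites)
    positions, _ = simulate_positions(cfg, chromosome - 1, seed)
    spec = MaternSpec.from_range_sigma(range_bp, sigma)
    y = simulate_track(positions, spec, sigma0, seed + 1000)
    return ChromosomeTrack(sample_id, chromosome, positions, y)


def make_iid_track(
    n_sites: int, sd: float = 1.0, seed: int = 0, sample_id: str = "s"
) -> ChromosomeTrack:
    cfg = CohortSimConfig(sites_per_chromosome=n_sites)
    positions, _ = simulate_positions(cfg, 0, seed)
    rng = np.random.default_rng(seed + 5000)
    return ChromosomeTrack(sample_id, 1, positions, rng.standard_normal(n_sites) * sd)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
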
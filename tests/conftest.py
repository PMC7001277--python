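import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wheatdiv import PopulationFrame, SimulationConfig, SnpMatrix
from wheatdiv import simulate_structured_genotypes

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_snp(columns, accession_prefix="A", marker_prefix="M"):
    """Build a SnpMatrix from a list of marker columns (lists of calls)."""
    cols = np.asarray(columns, dtype=np.int16).T
    n_acc, n_mark = cols.shape
    return SnpMatrix(
        [f"{accession_prefix}{i + 1}" for i in range(n_acc)],
        [f"{marker_prefix}{j + 1}" for j in range(n_mark)],
        cols,
    )


def two_pop_config(seed, fst=0.2, n=(50, 50), n_markers=2000, **kwargs):
    """Clean two-population Balding-Nichols collection (no injections)."""
    defaults = dict(
        n_populations=2, n_per_population=tuple(n), n_markers=n_markers,
        fst_target=fst, missing_rate=0.0, het_artifact_rate=0.0,
        duplicate_fraction=0.0, reference_set_size=0,
        n_chromosomes=2, chromosome_length_bp=100_000_000, seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture
def two_pop_fixture():
    """Matrix + frame for two populations of 50 at F=0.2, 2000 markers."""
    cfg = two_pop_config(seed=11)
    matrix, placements, frame, truth = simulate_structured_genotypes(cfg)
    return matrix, placements, frame, truth
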
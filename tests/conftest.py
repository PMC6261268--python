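import pandas as pd
import pytest

from atacage import AgingPopulationSpec, build_genome, simulate_atac_sample
from atacage.insertions import extract_insertions, normalize_track
from atacage.nucleosome import fit_size_components, pooled_size_distribution

GENOME_SEED = 1
LIVE_SEED = 2
N_FRAGMENTS = 200_000


@pytest.fixture(scope="session")
def genome():
    return build_genome(seed=GENOME_SEED)


@pytest.fixture(scope="session")
def live_fragments(genome) -> pd.DataFrame:
    """Live-cell-only default simulation at desk-scale depth."""
    return simulate_atac_sample(
        genome, AgingPopulationSpec(dead_fraction=0.0), N_FRAGMENTS, seed=LIVE_SEED
    )


@pytest.fixture(scope="session")
def live_track_raw(genome, live_fragments):
    return extract_insertions(live_fragments, genome.chrom_lengths)


@pytest.fixture(scope="session")
def live_track_norm(genome, live_track_raw):
    return normalize_track(live_track_raw, genome, target_total=1e6)


@pytest.fixture(scope="session")
def size_components(live_fragments):
    pooled = pooled_size_distribution([live_fragments])
    f_free, f_nuc = fit_size_components(pooled, split=115)
    return f_free, f_nuc
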
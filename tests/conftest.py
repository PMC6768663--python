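import pytest

from rhoscreen import LibraryComposition, SimParams, synthesize_manifest


@pytest.fixture(scope="session")
def screen_manifest():
    """Full-size manifest matching the screen's printed composition."""
    return synthesize_manifest(seed=1)


@pytest.fixture()
def small_composition():
    return LibraryComposition(n_gtpase=2, n_gef=1, n_gap=1, n_gdi=0,
                              n_scr_shrnas=2, min_shrnas_per_gene=2,
                              total_shrnas=12)


@pytest.fixture()
def small_manifest(small_composition):
    return synthesize_manifest(small_composition, seed=7)


@pytest.fixture()
def fast_params():
    """Scaled-down screen for cheap unit tests (not the study conditions)."""
    return SimParams(n_progenitors_per_embryo=3000, embryos_per_replicate=6,
                     reads_per_sample=100_000, seed=11)
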
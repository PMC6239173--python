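import numpy as np
import pytest

from srnakit import LibrarySpec, make_reference, simulate_library


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(
        n_families=3,
        n_insertions_per_family=2,
        n_mirnas=12,
        n_clusters=2,
        seed=42,
        family_len_range=(3000, 4000),
    )


@pytest.fixture(scope="session")
def mixed_library(small_ref):
    """A mid-sized library exercising every read class, with ground truth."""
    spec = LibrarySpec(
        n_reads=20_000,
        class_mix={
            "mirna": 0.25,
            "sirna_21": 0.30,
            "pirna_like": 0.20,
            "degradation": 0.20,
            "decoy": 0.05,
        },
        pingpong_rho=0.3,
        editing_rate=0.05,
        seq_error_rate=0.01,
        seed=7,
        library_id="mixlib",
    )
    reads, gt = simulate_library(spec, small_ref)
    return spec, reads, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
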
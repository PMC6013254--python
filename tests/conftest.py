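import pytest

from gpcrstab import BundleSpec, mini_receptor, synth_bundle


@pytest.fixture(scope="session")
def mini():
    """Serotonin-receptor-like miniature: (annotation, msas, target_id)."""
    return mini_receptor(seed=0)


@pytest.fixture(scope="session")
def small_bundle():
    """Three-helix toy bundle with annotation."""
    return synth_bundle(BundleSpec(n_helices=3, residues_per_helix=10, seed=1))


@pytest.fixture(scope="session")
def tiny_bundle():
    """Two-helix tight bundle (has disulfide-window pairs)."""
    return synth_bundle(
        BundleSpec(n_helices=2, residues_per_helix=10, radius=4.5, seed=3)
    )
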
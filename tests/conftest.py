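import pytest

from arffam.simulate import FamilyParams, simulate_family


@pytest.fixture(scope="session")
def bundle():
    """Paper-like synthetic bundle shared across tests (fixed seed)."""
    return simulate_family(seed=7)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The same bundle written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    simulate_family(seed=7, outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Bundle with zero Ct noise, for exact expression recovery checks."""
    return simulate_family(seed=7, params=FamilyParams(ct_noise_sd=0.0))
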
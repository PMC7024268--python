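import pytest
from hypothesis import settings

import pepdisrupt as pd
from pepdisrupt.synthetic import groove_hbond_specs

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_complex():
    """Receptor groove (14 residues) holding the L119-N130 stretch sequence."""
    return pd.make_toy_complex(14, "LSKDGFSKSMVN", seed=1)


@pytest.fixture(scope="session")
def toy_candidate(toy_complex):
    spans = pd.contiguous_stretches(
        pd.interface_residues(toy_complex, ["R"], "P"))
    cands = pd.rank_candidates(pd.excise_windows(
        toy_complex, "P", spans, (12, 12), receptor_chains=["R"]))
    return cands[0]


@pytest.fixture(scope="session")
def jittered_frames(toy_complex):
    """Ten geometrically varied frames (large jitter, no programmed bonds)."""
    ens = pd.make_ensemble(toy_complex, 10, [], jitter_sigma=0.6, seed=11)
    return list(ens)


@pytest.fixture()
def groove_specs(toy_complex):
    def _make(p):
        return groove_hbond_specs(toy_complex, p)
    return _make
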
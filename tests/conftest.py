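"""Shared fixtures: a synthetic benchmark compendium and its module calls."""

import pytest

import smap


@pytest.fixture(scope="session")
def synth():
    """Default synthetic compendium with planted on/off/background modules."""
    return smap.synth_compendium(seed=1)


@pytest.fixture(scope="session")
def calls(synth):
    """Module-call table on the synthetic compendium (truth-known)."""
    params = smap.ScoringParams(permutations=500, seed=1)
    return smap.score_and_classify(synth.modules, synth.compendium, params)


@pytest.fixture(scope="session")
def signature(synth, calls):
    by_id = {m.id: m for m in synth.modules}
    return smap.build_signature(calls, by_id, synth.compendium.universe())
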
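import pytest

from pvsignal.icsr_io import EventTarget
from pvsignal.synthetic import AF_PT_CODE, AF_PT_NAME, generate, oab_af_config


@pytest.fixture(scope="session")
def af_target() -> EventTarget:
    return EventTarget.of(AF_PT_CODE, [AF_PT_NAME])


@pytest.fixture(scope="session")
def jader_draw():
    """One modest JADER-style draw under the default study conditions."""
    cfg = oab_af_config("JADER", seed=11, n_cases=6000)
    raw, truth = generate(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def faers_draw():
    cfg = oab_af_config("FAERS", seed=12, n_cases=6000)
    raw, truth = generate(cfg)
    return cfg, raw, truth
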
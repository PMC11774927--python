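import numpy as np
import pytest

import channelspectra as cs
import channelspectra.experiments as ex


@pytest.fixture(scope="session")
def canonical_spec():
    """21-component multi-sine, T = 1 s, 0.25 mV, seeded phases."""
    return cs.make_stimulus(1.0, cs.CANONICAL_MULTIPLIERS, 0.25, rng_seed=0)


@pytest.fixture(scope="session")
def n4_qsa_run(canonical_spec):
    """Deterministic clamp response of the n^4 model at 5 mV plus its QSA
    estimate (shared across tests; dt = 0.02 ms)."""
    dt = 0.02
    y, si, base = ex.ode_clamp_response("n4", 5.0, canonical_spec, dt,
                                        observable="I_total")
    res = cs.estimate_qsa(canonical_spec, y, dt, si, base)
    return {"spec": canonical_spec, "dt": dt, "y": y, "start_index": si,
            "baseline": base, "result": res}


@pytest.fixture(scope="session")
def default_population():
    return cs.ChannelPopulation()
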
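import pytest
from hypothesis import HealthCheck, settings

from hdrscreen import io as hio

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: published per-construct screening counts: (construct, positive pools,
#: surviving G0, printed minimum integration rate %)
PRINTED_RATES = [
    ("190-perfect", 13, 271, 4.80),
    ("64+234-perfect", 8, 355, 2.25),
    ("234-recoded", 8, 339, 2.36),
    ("190-recoded", 3, 184, 1.63),
    ("190-recoded-ssDNA", 2, 174, 1.15),
    ("190-recoded-BTN-dsDNA", 2, 184, 1.09),
    ("190-recoded-BTN-ssDNA", 1, 178, 0.56),
]


@pytest.fixture(scope="session")
def example_table():
    return hio.load_example_experiment()


@pytest.fixture(scope="session")
def example_maps():
    return {name: hio.load_example_snp_map(name)
            for name in ("190-recoded", "234-recoded")}


@pytest.fixture(scope="session")
def example_events(example_maps):
    from hdrscreen.tracts import call_event
    events = []
    for name, snp_map in example_maps.items():
        for cs in hio.load_example_conversion_calls(name):
            events.append(call_event(cs, snp_map))
    return events
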
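import pytest

from timeuse_validation.catalog import (
    ActivityCatalog,
    ActivityCode,
    MethodRecord,
    build_default_catalog,
    build_grid,
)


@pytest.fixture(scope="session")
def catalog():
    return build_default_catalog()


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def toy_catalog():
    """Six activities, two simultaneous, spanning four divisions."""
    return ActivityCatalog(
        (
            ActivityCode("sim_care", "passive childcare", True, "MD4"),
            ActivityCode("sim_chat", "chatting", True, "MD7"),
            ActivityCode("cook", "cooking", False, "MD3"),
            ActivityCode("wash", "washing", False, "MD3"),
            ActivityCode("farm", "farming", False, "MD2"),
            ActivityCode("eat", "eating", False, "MD9"),
        )
    )


def make_record(slots, participant_id="P1", method="OBS", **kwargs):
    return MethodRecord(
        participant_id=participant_id,
        method=method,
        slots=tuple(frozenset(s) for s in slots),
        **kwargs,
    )


@pytest.fixture(scope="session")
def record_factory():
    return make_record
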
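import logging

import pytest

import sbgndyn as sd


@pytest.fixture(autouse=True)
def _quiet_expected_warnings(caplog):
    # random maps legitimately produce never-occurring processes; keep the
    # log readable while still allowing tests to assert on records
    logging.getLogger("sbgndyn").setLevel(logging.ERROR)
    yield
    logging.getLogger("sbgndyn").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def worked_example():
    return sd.fixture("worked_example")


@pytest.fixture(scope="session")
def worked_stories():
    return sd.StorySet([sd.Story({"a", "aP", "c"}, name="s"),
                        sd.Story({"adp", "atp"}, name="t")])


@pytest.fixture(scope="session")
def general_an(worked_example):
    return sd.encode(worked_example)


@pytest.fixture(scope="session")
def stories_an(worked_example, worked_stories):
    return sd.encode(worked_example, worked_stories)


@pytest.fixture(scope="session")
def general_stg(worked_example, general_an):
    init = sd.initial_global_state(general_an, worked_example,
                                   {"a", "atp", "b", "m"})
    return sd.build_stg(general_an, init)


@pytest.fixture(scope="session")
def stories_stg(worked_example, worked_stories, stories_an):
    init = sd.initial_global_state(stories_an, worked_example,
                                   {"a", "atp", "b", "m"}, worked_stories)
    return sd.build_stg(stories_an, init)


@pytest.fixture(scope="session")
def three_automata_an():
    return sd.fixture("three_automata_an")


@pytest.fixture(scope="session")
def three_automata_initial():
    return sd.GlobalState({"a": "0", "b": "1", "c": "0"})
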
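import pytest

from ribarriers import CrossingTable, load_study_fixture


@pytest.fixture(scope="session")
def study():
    """The packaged worked-example inputs (five barriers + assemblages)."""
    return load_study_fixture()


@pytest.fixture()
def tiny_crossing_table():
    """Two plants in one population, 2/10 and 4/10 outcross fruit set."""
    return CrossingTable.from_records(
        [
            dict(population="CO", plant_id="p1", treatment="xenogamy",
                 pollen_source="CO", flowers=10, fruits=2),
            dict(population="CO", plant_id="p2", treatment="xenogamy",
                 pollen_source="CO", flowers=10, fruits=4),
        ]
    )
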
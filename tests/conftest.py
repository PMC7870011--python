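import pytest

from canosa import synthetic


def small_scenario(**overrides) -> synthetic.Scenario:
    """A 3 x 400 kb scenario with the same event structure as the default:
    one copy-neutral LOH block, one deletion-LOH, one gain, scaled down."""
    base = dict(
        chrom_lengths={"1": 400_000, "2": 400_000, "3": 400_000},
        cna=[
            synthetic.CnaSpec("2", 0, 120_000, 1),
            synthetic.CnaSpec("3", 240_000, 300_000, 3),
        ],
        loh=[
            synthetic.LohSpec("1", 100_000, 200_000, "CN-neutral-LOH"),
            synthetic.LohSpec("2", 0, 120_000, "deletion-LOH"),
        ],
    )
    base.update(overrides)
    return synthetic.Scenario(**base)


@pytest.fixture(scope="session")
def small_truth():
    scenario = small_scenario()
    genome, sequences = synthetic.simulate_reference(
        scenario.chrom_lengths, gc=scenario.gc, seed=11
    )
    return synthetic.plant_truth(genome, sequences, scenario, seed=12)


@pytest.fixture(scope="session")
def default_truth():
    """Full-size (3 x 10 Mb) default scenario; shared across tests."""
    scenario = synthetic.Scenario()
    genome, sequences = synthetic.simulate_reference(
        scenario.chrom_lengths, gc=scenario.gc, seed=1
    )
    return synthetic.plant_truth(genome, sequences, scenario, seed=2)
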
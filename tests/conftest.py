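import pytest

from varsieve.fixtures import (
    FixtureSpec,
    generate_panel,
    generate_reference,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def std_fixture():
    """The standard seeded fixture: 10 kb, 200 SNVs, 20% repeats, H=20, s=25."""
    spec = FixtureSpec()
    ref = generate_reference(spec)
    variants, panel, _ = generate_panel(spec, ref)
    return spec, ref, variants, panel


@pytest.fixture(scope="session")
def small_fixture():
    """A faster 2 kb fixture for quadratic oracles."""
    spec = FixtureSpec(seed=7, genome_length=2000, n_variants=30,
                       repeat_fraction=0.3, window=12)
    ref = generate_reference(spec)
    variants, panel, _ = generate_panel(spec, ref)
    return spec, ref, variants, panel


@pytest.fixture(scope="session")
def worked(tmp_path_factory):
    """The GATYACA toy and the length-10 unique-4-mer bundle, as files."""
    return worked_example_fixture(tmp_path_factory.mktemp("worked"))


def naive_substring_counts(genome, s):
    """Independent s-mer counter: raw substring enumeration, skipping N."""
    from collections import Counter

    counts = Counter()
    for seq in genome.chromosomes.values():
        for i in range(len(seq) - s + 1):
            sub = seq[i:i + s]
            if "N" not in sub:
                counts[sub] += 1
    return counts
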
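import pytest

from dgepair import datasets
from dgepair.io import GeneCount, LibraryPair


@pytest.fixture
def small_counts():
    return [
        GeneCount("gA", 1000, 100, 400),
        GeneCount("gB", 500, 50, 55),
        GeneCount("gC", 2000, 300, 10),
        GeneCount("gD", 800, 0, 40),
        GeneCount("gE", 600, 0, 0),  # untestable
    ]


@pytest.fixture
def small_libs():
    return LibraryPair("L", "S", 1_000_000, 1_000_000)


@pytest.fixture(scope="session")
def reference_rows():
    return datasets.load_reference_rows()


@pytest.fixture(scope="session")
def reference_counts():
    return datasets.reference_counts()


def write_counts_text(path, text):
    path.write_text(text)
    return path
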
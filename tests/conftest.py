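import pytest

from ngome import HalfLifeTable, StructuralProfile, Weights


@pytest.fixture(scope="session")
def table():
    """The packaged dipeptide half-time table."""
    return HalfLifeTable.default()


@pytest.fixture(scope="session")
def tiny_table():
    """A two-entry table with round numbers for hand-checkable arithmetic."""
    return HalfLifeTable({"G": 1.0, "A": 20.0}, source_label="test")


@pytest.fixture(scope="session")
def published_weights():
    return Weights(helix=0.571, order=2.989)


def uniform_profile(length, h=0, d=1.0, sequence_id="p"):
    """Constant-track profile helper."""
    return StructuralProfile(
        sequence_id=sequence_id,
        helix=(h,) * length,
        disorder=(d,) * length,
        provenance="parsed-external",
    )


@pytest.fixture
def flat_profile():
    return uniform_profile
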
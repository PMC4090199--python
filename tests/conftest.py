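import pytest

from pathassoc import PathwayDB


def make_db(sizes, prefix="g"):
    """Disjoint pathways of the given sizes over a fresh gene universe."""
    pathways = {}
    counter = 0
    for i, s in enumerate(sizes):
        pathways[f"P{i + 1}"] = (
            f"pathway {i + 1}",
            {f"{prefix}{counter + j}" for j in range(s)},
        )
        counter += s
    return PathwayDB(pathways)


@pytest.fixture
def toy_db():
    """Two overlapping pathways over an 8-gene universe; the pooled tail at
    (k=2, G=2) is 21/56 by enumeration of all 28 gene pairs."""
    return PathwayDB(
        {
            "P1": ("first", {"g1", "g2", "g3", "g4"}),
            "P2": ("second", {"g3", "g4", "g5", "g6", "g7", "g8"}),
        }
    )


@pytest.fixture
def disjoint_db():
    return make_db([4, 6, 8, 10])
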
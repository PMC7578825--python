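import numpy as np
import pandas as pd
import pytest

from trophicniche.datatypes import DietMatrix, IsotopeTable


@pytest.fixture
def two_specialists() -> DietMatrix:
    """Two individuals each monopolizing one of two taxa."""
    return DietMatrix(
        pd.DataFrame(
            {
                "individual_id": ["i1", "i2"],
                "group": ["g", "g"],
                "prey_taxon": ["a", "b"],
                "count": [10, 10],
                "mass": [1.0, 1.0],
            }
        )
    )


@pytest.fixture
def counts_8_2() -> DietMatrix:
    """Counts [[8, 2], [2, 8]]: the worked entropy-decomposition example."""
    rows = []
    for ind, counts in (("i1", (8, 2)), ("i2", (2, 8))):
        for taxon, c in zip("ab", counts):
            rows.append(
                dict(individual_id=ind, group="g", prey_taxon=taxon,
                     count=c, mass=float(c))
            )
    return DietMatrix(pd.DataFrame(rows))


def make_isotable(points, group="g") -> IsotopeTable:
    pts = np.asarray(points, dtype=float)
    return IsotopeTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(pts))],
                "group": group,
                "d13C": pts[:, 0],
                "d15N": pts[:, 1],
            }
        )
    )


@pytest.fixture
def isotable_345() -> IsotopeTable:
    """Points (0,0) and (3,4): hand-geometry example for the Layman metrics."""
    return make_isotable([(0, 0), (3, 4)])
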
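import numpy as np
import pandas as pd
import pytest

from traitcooc.io import IncidenceMatrix, TraitTable


@pytest.fixture
def tiny_matrix() -> IncidenceMatrix:
    """3 species × 4 lakes with mixed overlap."""
    cells = np.array(
        [
            [1, 1, 1, 0],
            [0, 0, 1, 1],
            [1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return IncidenceMatrix("w1", ("a", "b", "c"), ("l1", "l2", "l3", "l4"), cells)


@pytest.fixture
def simple_traits() -> TraitTable:
    df = pd.DataFrame(
        {
            "genus": ["Esox", "Esox", "Perca", "Perca", "Salmo"],
            "body_size": [100.0, 60.0, 25.0, 30.0, 55.0],
            "temp_pref": [19.0, 21.0, 23.0, np.nan, 12.0],
            "trophic_level": [4.2, 4.0, 3.4, 3.2, 3.8],
        },
        index=pd.Index(["e1", "e2", "p1", "p2", "s1"], name="species_id"),
    )
    return TraitTable(df)


def random_incidence(
    rng: np.random.Generator,
    n_species: int,
    n_lakes: int,
    fill: float = 0.4,
    watershed_id: str = "w",
) -> IncidenceMatrix:
    """Random binary matrix with no all-zero rows (resampled as needed)."""
    while True:
        cells = (rng.random((n_species, n_lakes)) < fill).astype(np.int8)
        if (cells.sum(axis=1) > 0).all():
            return IncidenceMatrix(
                watershed_id,
                tuple(f"s{i}" for i in range(n_species)),
                tuple(f"l{j}" for j in range(n_lakes)),
                cells,
            )
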
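import pandas as pd
import pytest

from taxbeta.community import OccurrenceTable, TaxonomyTable


@pytest.fixture
def tiny_occurrences() -> OccurrenceTable:
    """One group, two species, two sites; includes a zero-record row."""
    df = pd.DataFrame(
        [
            ("amphibia", "Lithobates berlandieri", "MF", 2),
            ("amphibia", "Anaxyrus compactilis", "MF", 0),
            ("amphibia", "Anaxyrus compactilis", "VB", 5),
        ],
        columns=["group", "species", "site", "records"],
    )
    return OccurrenceTable(df)


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    """Three species in two genera / two families, one ragged lineage."""
    df = pd.DataFrame(
        [
            ("famX", "genA", "sp a1"),
            ("famX", "genA", "sp a2"),
            ("famY", "", "sp b1"),  # genus not applicable for this lineage
        ],
        columns=["family", "genus", "species"],
    )
    return TaxonomyTable(group="g", ranks=("family", "genus", "species"), assignments=df)


@pytest.fixture
def three_site_incidence():
    """Sites A={1,2}, B={2,3}, C={3,4}: the hand-enumerable worked example."""
    from taxbeta.community import IncidenceMatrix

    presence = pd.DataFrame(
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]],
        index=["A", "B", "C"],
        columns=["e1", "e2", "e3", "e4"],
    )
    return IncidenceMatrix(group="toy", presence=presence)
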
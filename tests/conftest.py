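import numpy as np
import pandas as pd
import pytest

from mycoassembly.datamodel import (
    CommunityTable,
    SampleMetadata,
    TableMode,
    TaxonAnnotation,
    taxonomy_to_cladogram,
)
from mycoassembly.synthetic import sample_metacommunity


@pytest.fixture
def small_counts() -> CommunityTable:
    df = pd.DataFrame(
        [[10.0, 0.0, 5.0], [2.0, 3.0, 0.0], [1.0, 1.0, 1.0]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["t1", "t2", "t3"],
    )
    return CommunityTable(df, TableMode.counts)


@pytest.fixture
def small_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "compartment": ["leaf", "root", "soil"],
                "week": [1, 2, 3],
                "treatment": ["control", "control", "control"],
            }
        )
    )


@pytest.fixture
def two_genus_annotation() -> TaxonAnnotation:
    """Two OTUs in one genus, one distant OTU sharing only the kingdom."""
    return TaxonAnnotation(
        pd.DataFrame(
            {
                "taxon_id": ["t1", "t2", "t3"],
                "kingdom": ["Fungi"] * 3,
                "phylum": ["Asco", "Asco", "Basidio"],
                "class": ["c1", "c1", "c2"],
                "order": ["o1", "o1", "o2"],
                "family": ["f1", "f1", "f2"],
                "genus": ["g1", "g1", "g2"],
                "guild": ["saprotroph", "yeast", "plant_pathogen"],
            }
        )
    )


@pytest.fixture
def two_genus_tree(two_genus_annotation):
    return taxonomy_to_cladogram(two_genus_annotation)


@pytest.fixture(scope="session")
def pool():
    """Small metacommunity shared by the slower simulation tests."""
    return sample_metacommunity(S=80, lognormal_sigma=1.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
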
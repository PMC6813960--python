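import numpy as np
import pandas as pd
import pytest

from biogeocycler import OtuTable, load_marker_config


@pytest.fixture(scope="session")
def marker_config():
    """The packaged default marker-gene configuration."""
    return load_marker_config()


@pytest.fixture
def toy_otu_table():
    """3 samples x 4 OTUs with two phyla, hand-checkable."""
    counts = pd.DataFrame(
        [[5, 1, 1, 2], [3, 3, 3, 3], [8, 2, 0, 0]],
        index=["S1", "S2", "S3"],
        columns=["OTU1", "OTU2", "OTU3", "OTU4"],
    )
    lineage = pd.Series(
        {
            "OTU1": "Bacteria;Proteobacteria;Gamma;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
            "OTU2": "Bacteria;Proteobacteria;Alpha;Rhizobiales;Bradyrhizobiaceae;Bradyrhizobium",
            "OTU3": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Anoxybacillus",
            "OTU4": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus",
        }
    )
    return OtuTable(counts=counts, lineage=lineage)


def make_otu(counts: np.ndarray, samples=None, otus=None) -> OtuTable:
    """Quick OtuTable from an array with placeholder lineages."""
    counts = np.asarray(counts)
    samples = samples or [f"S{i+1}" for i in range(counts.shape[0])]
    otus = otus or [f"O{i+1}" for i in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=samples, columns=otus)
    lineage = pd.Series({o: f"Bacteria;P;C;O;F;G{i}" for i, o in enumerate(otus)})
    return OtuTable(counts=frame, lineage=lineage)
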
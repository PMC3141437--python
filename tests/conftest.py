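import numpy as np
import pandas as pd
import pytest

from pancestor.datamodel import GenomeRecord, OrthologMatrix
from pancestor.trees import Phylogeny


@pytest.fixture
def quartet_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tiny_matrix():
    """Five genomes (three finished), hand-checkable counts.

    g1..g3 finished (clade1, clade1, clade2), g4..g5 drafts (clade2).
    g1 and g2 are filamentous; g2 is also heterocystous.
    """
    genomes = {
        "g1": GenomeRecord(id="g1", finished=True, clade="clade1",
                           phenotypes={"filamentous"}),
        "g2": GenomeRecord(id="g2", finished=True, clade="clade1",
                           phenotypes={"filamentous", "heterocystous"}),
        "g3": GenomeRecord(id="g3", finished=True, clade="clade2"),
        "g4": GenomeRecord(id="g4", finished=False, clade="clade2"),
        "g5": GenomeRecord(id="g5", finished=False, clade="clade2"),
    }
    cols = list(genomes)
    functional = pd.DataFrame(
        # G1: everywhere; G2: absent in finished g3; G3: pseudo-only in g1;
        # G4: filamentous-exclusive; G5: paralogous in g1; G6: absent in drafts
        [
            [1, 1, 1, 1, 1],
            [1, 1, 0, 1, 1],
            [0, 2, 1, 1, 1],
            [1, 1, 0, 0, 0],
            [3, 1, 1, 1, 1],
            [1, 1, 1, 0, 0],
        ],
        index=[f"G{i}" for i in range(1, 7)],
        columns=cols,
    )
    pseudo = pd.DataFrame(
        [
            [0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
            [0, 0, 0, 0, 0],
        ],
        index=functional.index,
        columns=cols,
    )
    return OrthologMatrix(functional, pseudo, genomes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
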
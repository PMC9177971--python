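import numpy as np
import pytest

import hetsilence as hs
from hetsilence.genome import GeneModel, GenomeAnnotation


@pytest.fixture(scope="session")
def toy_ann():
    return hs.toy_annotation()


@pytest.fixture()
def mini_ann():
    """Tiny hand-built annotation: 3 plain genes, one with an intron,
    a 2-copy repeat family, and one rRNA gene on a 10 kb chromosome."""
    genes = [
        GeneModel("gA", "chr1", 100, 1100, "+", "protein_coding"),
        GeneModel("gB", "chr1", 1500, 2500, "-", "protein_coding",
                  exons=[(1500, 1900), (2100, 2500)]),
        GeneModel("gC", "chr1", 3000, 4000, "+", "subtelomeric"),
        GeneModel("rep1", "chr1", 5000, 5600, "+", "dg", copy_group="fam",
                  is_representative=True),
        GeneModel("rep2", "chr1", 6000, 6600, "+", "dg", copy_group="fam"),
        GeneModel("rrn", "chr1", 8000, 8800, "+", "rRNA"),
    ]
    return GenomeAnnotation(genes, {"chr1": 10000})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
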
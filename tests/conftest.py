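import numpy as np
import pytest

from ssrmarkers.genotypes import MISSING, Accession, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_matrix():
    """4 accessions x 3 loci, with a heterozygote, a missing call and one
    accession pair sharing an identical profile."""
    accessions = [
        Accession("A1", "P. somniferum", "somniferum"),
        Accession("A2", "P. somniferum", "somniferum"),
        Accession("A3", "P. somniferum", "culinary"),
        Accession("A4", "P. somniferum", "culinary"),
    ]
    loci = ["L1", "L2", "L3"]
    calls = {
        ("A1", "L1"): ("152", "152"),
        ("A1", "L2"): ("200", "206"),
        ("A1", "L3"): ("101", "101"),
        ("A2", "L1"): ("152", "158"),
        ("A2", "L2"): ("200", "200"),
        ("A2", "L3"): MISSING,
        ("A3", "L1"): ("152", "152"),
        ("A3", "L2"): ("200", "206"),
        ("A3", "L3"): ("101", "101"),
        ("A4", "L1"): ("158", "158"),
        ("A4", "L2"): ("206", "206"),
        ("A4", "L3"): ("104", "104"),
    }
    return GenotypeMatrix(accessions, loci, calls)
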
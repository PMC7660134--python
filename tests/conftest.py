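import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from protloc.io import GenomeAnnotation


@pytest.fixture()
def toy_annotation() -> GenomeAnnotation:
    """Two genes on a 10 kb pseudo-chromosome, one per strand.

    geneA (+): 5'UTR [1000,1050), ORF [1050,1500), intron [1500,1600),
    3'UTR [1600,1700).  geneB (-): mirrored layout with the TSS at the
    high-coordinate end.
    """
    regions = pd.DataFrame(
        [
            ("geneA", "five_prime_utr", "chrS", 1000, 1050, "+"),
            ("geneA", "orf", "chrS", 1050, 1500, "+"),
            ("geneA", "intron", "chrS", 1500, 1600, "+"),
            ("geneA", "three_prime_utr", "chrS", 1600, 1700, "+"),
            ("geneB", "three_prime_utr", "chrS", 3000, 3100, "-"),
            ("geneB", "intron", "chrS", 3100, 3200, "-"),
            ("geneB", "orf", "chrS", 3200, 3650, "-"),
            ("geneB", "five_prime_utr", "chrS", 3650, 3700, "-"),
        ],
        columns=["gene_id", "region_role", "chrom", "start", "end", "strand"],
    )
    return GenomeAnnotation(regions=regions, chrom_sizes={"chrS": 10000})


@pytest.fixture()
def barcode_map() -> dict:
    return {"GGCTA": "s1", "TTAGC": "s2"}


def random_track(rng, max_positions=50, max_count=20):
    """A random sparse strand track: sorted distinct positions with counts."""
    n = int(rng.integers(1, max_positions + 1))
    positions = np.sort(rng.choice(200, size=n, replace=False)).astype(int)
    values = rng.integers(1, max_count + 1, size=n).astype(int)
    return positions, values
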
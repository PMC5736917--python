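"""Bundled Saccharomyces cerevisiae genome constants.

Chromosome lengths and centromere midpoints follow the SGD R64 reference
assembly (1-based coordinates). Any :func:`meiorec.genome.make_genome_layout`
call can override these with explicit lengths/centromeres.
"""
from __future__ import annotations

import pandas as pd

# name, length (bp), centromere midpoint (bp)
_YEAST_CHROMOSOMES = [
    ("chrI", 230_218, 151_465),
    ("chrII", 813_184, 238_207),
    ("chrIII", 316_620, 114_385),
    ("chrIV", 1_531_933, 449_711),
    ("chrV", 576_874, 151_987),
    ("chrVI", 270_161, 148_510),
    ("chrVII", 1_090_940, 496_920),
    ("chrVIII", 562_643, 105_586),
    ("chrIX", 439_888, 355_629),
    ("chrX", 745_751, 436_307),
    ("chrXI", 666_816, 440_129),
    ("chrXII", 1_078_177, 150_828),
    ("chrXIII", 924_431, 268_031),
    ("chrXIV", 784_333, 628_758),
    ("chrXV", 1_091_291, 326_584),
    ("chrXVI", 948_066, 555_957),
]


def yeast_chromosome_table() -> pd.DataFrame:
    """Return the 16 yeast chromosomes as a DataFrame (name, length, centromere)."""
    return pd.DataFrame(_YEAST_CHROMOSOMES, columns=["name", "length", "centromere"])


#: Total haploid genome length of the bundled assembly (~12.07 Mb).
YEAST_GENOME_LENGTH = sum(length for _, length, _ in _YEAST_CHROMOSOMES)
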
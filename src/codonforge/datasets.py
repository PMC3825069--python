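"""Published pooled codon-usage tables bundled for worked examples.

Pooled codon counts over the filtered protein-coding gene sets of two
freshwater cyanobacterial-type genomes, as published:

* ``PAULINELLA_CHROMATOPHORE`` — the 786 filtered CDS of the
  *Paulinella chromatophora* chromatophore genome (GenBank NC_011087.1),
  an AT-rich photosynthetic organelle genome.
* ``SYNECHOCOCCUS_ELONGATUS`` — the 2342 filtered CDS of
  *Synechococcus elongatus* PCC6301 (GenBank AP008231), a GC-rich
  free-living beta-cyanobacterium.

These are *inputs* (published count tables), useful for desk-scale
checks of RSCU arithmetic without downloading either genome.
"""

from __future__ import annotations

from .counts import CodonCountTable

PAULINELLA_CHROMATOPHORE_COUNTS = {
    "TTT": 6873, "TTC": 2665, "TTA": 10679, "TTG": 4586,
    "CTT": 6933, "CTC": 2001, "CTA": 5010, "CTG": 1961,
    "ATT": 9871, "ATC": 3060, "ATA": 6960, "ATG": 5377,
    "GTT": 5473, "GTC": 2078, "GTA": 6876, "GTG": 1941,
    "TCT": 4800, "TCC": 1460, "TCA": 3346, "TCG": 912,
    "AGT": 5768, "AGC": 2262,
    "CCT": 5240, "CCC": 1350, "CCA": 4110, "CCG": 916,
    "ACT": 5928, "ACC": 1789, "ACA": 4202, "ACG": 1300,
    "GCT": 9187, "GCC": 2787, "GCA": 6221, "GCG": 1670,
    "TAT": 4818, "TAC": 1810,
    "CAT": 4076, "CAC": 1209,
    "CAA": 7465, "CAG": 2993,
    "AAT": 8988, "AAC": 2507,
    "AAA": 8697, "AAG": 3498,
    "GAT": 9705, "GAC": 2379,
    "GAA": 11405, "GAG": 4189,
    "TGT": 2292, "TGC": 922, "TGG": 3689,
    "CGT": 5325, "CGC": 1765, "CGA": 2696, "CGG": 892,
    "AGA": 3524, "AGG": 1169,
    "GGT": 7794, "GGC": 2836, "GGA": 6200, "GGG": 2129,
    "TAA": 439, "TAG": 144, "TGA": 203,
}

SYNECHOCOCCUS_ELONGATUS_COUNTS = {
    "TTT": 14909, "TTC": 11811, "TTA": 6634, "TTG": 19535,
    "CTT": 7121, "CTC": 20585, "CTA": 8678, "CTG": 32548,
    "ATT": 20131, "ATC": 21038, "ATA": 692, "ATG": 11456,
    "GTT": 12236, "GTC": 17788, "GTA": 3535, "GTG": 18179,
    "TCT": 4946, "TCC": 5912, "TCA": 4257, "TCG": 9207,
    "AGT": 9128, "AGC": 13096,
    "CCT": 7920, "CCC": 14372, "CCA": 7251, "CCG": 13017,
    "ACT": 7789, "ACC": 15479, "ACA": 5513, "ACG": 11432,
    "GCT": 19671, "GCC": 25932, "GCA": 14455, "GCG": 21572,
    "TAT": 8278, "TAC": 10678,
    "CAT": 6464, "CAC": 6949,
    "CAA": 23338, "CAG": 24092,
    "AAT": 10381, "AAC": 10858,
    "AAA": 10248, "AAG": 9370,
    "GAT": 25896, "GAC": 13769,
    "GAA": 24927, "GAG": 18827,
    "TGT": 3451, "TGC": 4905, "TGG": 13533,
    "CGT": 7985, "CGC": 23748, "CGA": 7940, "CGG": 11080,
    "AGA": 1135, "AGG": 791,
    "GGT": 14414, "GGC": 24840, "GGA": 6797, "GGG": 9975,
    "TAA": 776, "TAG": 922, "TGA": 707,
}


def paulinella_pooled_counts() -> CodonCountTable:
    """Pooled codon counts of the chromatophore genome's 786 CDS."""
    return CodonCountTable(
        PAULINELLA_CHROMATOPHORE_COUNTS, source_ids=("NC_011087.1",)
    )


def synechococcus_pooled_counts() -> CodonCountTable:
    """Pooled codon counts of the *S. elongatus* PCC6301 2342 CDS."""
    return CodonCountTable(
        SYNECHOCOCCUS_ELONGATUS_COUNTS, source_ids=("AP008231",)
    )
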
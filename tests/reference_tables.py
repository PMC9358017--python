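"""Frozen reference S/NS site values for the standard genetic code.

Independently tabulated (by hand enumeration of the nine single-base
neighbors of every sense codon) for the equal-rate method and for the
kappa = 4 transition-weighted, nonsense-corrected method.  Values are
rounded half-away-from-zero to 3 decimals.  Tests compare the package's
computed tables cell by cell against these.
"""

# codon -> (S, NS), equal-rate ("old") method
OLD_SITES = {
    # TTN / TCN / TAN / TGN
    "TTT": (0.333, 2.667), "TTC": (0.333, 2.667), "TTA": (0.667, 2.333), "TTG": (0.667, 2.333),
    "TCT": (1.000, 2.000), "TCC": (1.000, 2.000), "TCA": (1.000, 2.000), "TCG": (1.000, 2.000),
    "TAT": (0.333, 2.667), "TAC": (0.333, 2.667),
    "TGT": (0.333, 2.667), "TGC": (0.333, 2.667), "TGG": (0.000, 3.000),
    # CTN / CCN / CAN / CGN
    "CTT": (1.000, 2.000), "CTC": (1.000, 2.000), "CTA": (1.333, 1.667), "CTG": (1.333, 1.667),
    "CCT": (1.000, 2.000), "CCC": (1.000, 2.000), "CCA": (1.000, 2.000), "CCG": (1.000, 2.000),
    "CAT": (0.333, 2.667), "CAC": (0.333, 2.667), "CAA": (0.333, 2.667), "CAG": (0.333, 2.667),
    "CGT": (1.000, 2.000), "CGC": (1.000, 2.000), "CGA": (1.333, 1.667), "CGG": (1.333, 1.667),
    # ATN / ACN / AAN / AGN
    "ATT": (0.667, 2.333), "ATC": (0.667, 2.333), "ATA": (0.667, 2.333), "ATG": (0.000, 3.000),
    "ACT": (1.000, 2.000), "ACC": (1.000, 2.000), "ACA": (1.000, 2.000), "ACG": (1.000, 2.000),
    "AAT": (0.333, 2.667), "AAC": (0.333, 2.667), "AAA": (0.333, 2.667), "AAG": (0.333, 2.667),
    "AGT": (0.333, 2.667), "AGC": (0.333, 2.667), "AGA": (0.667, 2.333), "AGG": (0.667, 2.333),
    # GTN / GCN / GAN / GGN
    "GTT": (1.000, 2.000), "GTC": (1.000, 2.000), "GTA": (1.000, 2.000), "GTG": (1.000, 2.000),
    "GCT": (1.000, 2.000), "GCC": (1.000, 2.000), "GCA": (1.000, 2.000), "GCG": (1.000, 2.000),
    "GAT": (0.333, 2.667), "GAC": (0.333, 2.667), "GAA": (0.333, 2.667), "GAG": (0.333, 2.667),
    "GGT": (1.000, 2.000), "GGC": (1.000, 2.000), "GGA": (1.000, 2.000), "GGG": (1.000, 2.000),
}

# codon -> (S, NS'), kappa = 4 modified method (nonsense substitutions removed)
MODIFIED_SITES_K4 = {
    "TTT": (0.667, 2.333), "TTC": (0.667, 2.333), "TTA": (1.333, 1.333), "TTG": (1.333, 1.500),
    "TCT": (1.000, 2.000), "TCC": (1.000, 2.000), "TCA": (1.000, 1.667), "TCG": (1.000, 1.833),
    "TAT": (0.667, 2.000), "TAC": (0.667, 2.000),
    "TGT": (0.667, 2.167), "TGC": (0.667, 2.167), "TGG": (0.000, 1.667),
    "CTT": (1.000, 2.000), "CTC": (1.000, 2.000), "CTA": (1.667, 1.333), "CTG": (1.667, 1.333),
    "CCT": (1.000, 2.000), "CCC": (1.000, 2.000), "CCA": (1.000, 2.000), "CCG": (1.000, 2.000),
    "CAT": (0.667, 2.333), "CAC": (0.667, 2.333), "CAA": (0.667, 1.667), "CAG": (0.667, 1.667),
    "CGT": (1.000, 2.000), "CGC": (1.000, 2.000), "CGA": (1.167, 1.167), "CGG": (1.167, 1.833),
    "ATT": (0.833, 2.167), "ATC": (0.833, 2.167), "ATA": (0.333, 2.667), "ATG": (0.000, 3.000),
    "ACT": (1.000, 2.000), "ACC": (1.000, 2.000), "ACA": (1.000, 2.000), "ACG": (1.000, 2.000),
    "AAT": (0.667, 2.333), "AAC": (0.667, 2.333), "AAA": (0.667, 2.167), "AAG": (0.667, 2.167),
    "AGT": (0.667, 2.333), "AGC": (0.667, 2.333), "AGA": (0.833, 2.000), "AGG": (0.833, 2.167),
    "GTT": (1.000, 2.000), "GTC": (1.000, 2.000), "GTA": (1.000, 2.000), "GTG": (1.000, 2.000),
    "GCT": (1.000, 2.000), "GCC": (1.000, 2.000), "GCA": (1.000, 2.000), "GCG": (1.000, 2.000),
    "GAT": (0.667, 2.333), "GAC": (0.667, 2.333), "GAA": (0.667, 2.167), "GAG": (0.667, 2.167),
    "GGT": (1.000, 2.000), "GGC": (1.000, 2.000), "GGA": (1.000, 1.833), "GGG": (1.000, 2.000),
}
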
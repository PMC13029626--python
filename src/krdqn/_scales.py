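"""Per-residue physicochemical scales for protein-composition features.

Twelve standard published scales over the 20 canonical amino acids, in the
fixed residue order A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y:

1.  Kyte-Doolittle hydropathy (J Mol Biol 1982)
2.  Residue volume, A^3 (Zamyatnin 1972)
3.  Polarity (Grantham 1974)
4.  Isoelectric point of the free amino acid (Zimmerman 1968)
5.  Flexibility, average B-value normalised (Vihinen 1994)
6.  Bulkiness (Zimmerman 1968)
7.  Aromaticity indicator (1 for F,W,Y,H; else 0)
8.  Net side-chain charge at pH 7 (D,E = -1; K,R = +1; H = +0.1)
9.  Side-chain hydrogen-bond donor count
10. Maximum solvent-accessible surface area, A^2 (Tien et al. 2013)
11. Alpha-helix propensity P_alpha (Chou-Fasman 1978)
12. Beta-sheet propensity P_beta (Chou-Fasman 1978)
"""
from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SCALES = {
    #        KD     vol   pol    pI   flex   bulk  arom  chg  don   asa   Pa    Pb
    "A": ( 1.8,   88.6,  8.1,  6.00, 0.984, 11.50, 0.0,  0.0, 0.0, 129.0, 1.42, 0.83),
    "C": ( 2.5,  108.5,  5.5,  5.05, 0.906, 13.46, 0.0,  0.0, 1.0, 167.0, 0.70, 1.19),
    "D": (-3.5,  111.1, 13.0,  2.77, 1.068, 11.68, 0.0, -1.0, 1.0, 193.0, 1.01, 0.54),
    "E": (-3.5,  138.4, 12.3,  3.22, 1.094, 13.57, 0.0, -1.0, 1.0, 223.0, 1.51, 0.37),
    "F": ( 2.8,  189.9,  5.2,  5.48, 0.915, 19.80, 1.0,  0.0, 0.0, 240.0, 1.13, 1.38),
    "G": (-0.4,   60.1,  9.0,  5.97, 1.031,  3.40, 0.0,  0.0, 0.0, 104.0, 0.57, 0.75),
    "H": (-3.2,  153.2, 10.4,  7.59, 0.950, 13.69, 1.0,  0.1, 1.0, 224.0, 1.00, 0.87),
    "I": ( 4.5,  166.7,  5.2,  6.02, 0.927, 21.40, 0.0,  0.0, 0.0, 197.0, 1.08, 1.60),
    "K": (-3.9,  168.6, 11.3,  9.74, 1.102, 15.71, 0.0,  1.0, 2.0, 236.0, 1.16, 0.74),
    "L": ( 3.8,  166.7,  4.9,  5.98, 0.935, 21.40, 0.0,  0.0, 0.0, 201.0, 1.21, 1.30),
    "M": ( 1.9,  162.9,  5.7,  5.74, 0.952, 16.25, 0.0,  0.0, 0.0, 224.0, 1.45, 1.05),
    "N": (-3.5,  114.1, 11.6,  5.41, 1.048, 12.82, 0.0,  0.0, 2.0, 195.0, 0.67, 0.89),
    "P": (-1.6,  112.7,  8.0,  6.30, 1.049, 17.43, 0.0,  0.0, 0.0, 159.0, 0.57, 0.55),
    "Q": (-3.5,  143.8, 10.5,  5.65, 1.037, 14.45, 0.0,  0.0, 2.0, 225.0, 1.11, 1.10),
    "R": (-4.5,  173.4, 10.5, 10.76, 1.008, 14.28, 0.0,  1.0, 4.0, 274.0, 0.98, 0.93),
    "S": (-0.8,   89.0,  9.2,  5.68, 1.046,  9.47, 0.0,  0.0, 1.0, 155.0, 0.77, 0.75),
    "T": (-0.7,  116.1,  8.6,  5.60, 0.997, 15.77, 0.0,  0.0, 1.0, 172.0, 0.83, 1.19),
    "V": ( 4.2,  140.0,  5.9,  5.96, 0.931, 21.57, 0.0,  0.0, 0.0, 174.0, 1.06, 1.70),
    "W": (-0.9,  227.8,  5.4,  5.89, 0.904, 21.67, 1.0,  0.0, 1.0, 285.0, 1.08, 1.37),
    "Y": (-1.3,  193.6,  6.2,  5.66, 0.929, 18.03, 1.0,  0.0, 1.0, 263.0, 0.69, 1.47),
}

N_SCALES = 12

#: (20, 12) matrix of scale values in AMINO_ACIDS order
SCALE_MATRIX = np.array([_SCALES[a] for a in AMINO_ACIDS], dtype=float)
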
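"""Pinned per-residue scale tables used by the property calculators.

Values are vendored verbatim from the primary literature so that property
scores are reproducible independent of external tool versions:

- KYTE_DOOLITTLE: Kyte & Doolittle (1982) J Mol Biol 157:105 hydropathy index.
- CHOU_FASMAN_TURN: Chou & Fasman (1978) beta-turn conformational propensities.
- EMINI: Emini et al. (1985) J Virol 55:836 surface fractional probabilities.
- KARPLUS_SCHULZ: Karplus & Schulz (1985) Naturwissenschaften 72:212
  flexibility (normalized B-factors, no rigid neighbours).
- PARKER: Parker, Guo & Hodges (1986) Biochemistry 25:5425 HPLC-derived
  hydrophilicity.
"""

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHOU_FASMAN_TURN = {
    "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19,
    "Q": 0.98, "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47,
    "L": 0.59, "K": 1.01, "M": 0.60, "F": 0.60, "P": 1.52,
    "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.50,
}

EMINI = {
    "A": 0.49, "R": 0.95, "N": 0.81, "D": 0.78, "C": 0.26,
    "Q": 0.84, "E": 0.84, "G": 0.48, "H": 0.66, "I": 0.34,
    "K": 0.97, "L": 0.40, "M": 0.48, "F": 0.42, "P": 0.75,
    "S": 0.65, "T": 0.70, "W": 0.51, "Y": 0.76, "V": 0.36,
}

KARPLUS_SCHULZ = {
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906,
    "Q": 1.037, "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927,
    "L": 0.935, "K": 1.102, "M": 0.952, "F": 0.915, "P": 1.049,
    "S": 1.046, "T": 0.997, "W": 0.904, "Y": 0.929, "V": 0.931,
}

PARKER = {
    "A": 2.1, "R": 4.2, "N": 7.0, "D": 10.0, "C": 1.4,
    "Q": 6.0, "E": 7.8, "G": 5.7, "H": 2.1, "I": -8.0,
    "K": 5.7, "L": -9.2, "M": -4.2, "F": -9.2, "P": 2.1,
    "S": 6.5, "T": 5.2, "W": -10.0, "Y": -1.9, "V": -3.7,
}

# Residue groupings for secondary-structure fractions: helix after Haimov &
# Srebnik (2016), turn after Hutchinson & Thornton (1994), sheet after Kim &
# Berg (1993) — the corrected groupings current ProtParam also uses.
HELIX_RESIDUES = frozenset("EMALK")
TURN_RESIDUES = frozenset("NPGSD")
SHEET_RESIDUES = frozenset("VIYFWLT")

AROMATIC_RESIDUES = frozenset("FWY")

# Bjellqvist et al. (1993, 1994) pKa set for the Henderson-Hasselbalch
# net-charge function, including the residue-specific terminal adjustments.
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
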
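"""Physical constants and lookup tables used across the package.

All masses are in daltons (Da); mass-to-charge values in thomson (Th).
Isotope masses and abundances are the standard IUPAC 2013 values for the
five elements of the averagine model (C, H, N, O, S).
"""

from __future__ import annotations

#: Mass of a proton (positive-mode charge carrier), Da.
PROTON_MASS = 1.007276

#: Centroided spacing between adjacent isotopomer peaks of a singly charged
#: ion, Da.  This is the conventional "averagine" spacing, not the physical
#: neutron mass; at charge z the peak spacing is ISOTOPE_SPACING / z Th.
ISOTOPE_SPACING = 1.00235

#: Monoisotopic masses of the two common neutral losses, Da.
H2O_MASS = 18.010565
NH3_MASS = 17.026549

#: Averagine unit composition (fractional atoms per average residue) and its
#: average mass, after Senko et al.  Used to estimate an elemental
#: composition from a mass alone.
AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_UNIT_MASS = 111.1254

#: Per-element isotope tables: neutron-count shift -> (mass Da, abundance).
#: Shift 0 is the most abundant (and lightest) isotope for all of C,H,N,O,S,
#: so the monoisotopic mass is the shift-0 sum.
ISOTOPES = {
    "C": {0: (12.0, 0.9893), 1: (13.0033548, 0.0107)},
    "H": {0: (1.0078250319, 0.999885), 1: (2.0141017780, 0.000115)},
    "N": {0: (14.0030740052, 0.99636), 1: (15.0001088984, 0.00364)},
    "O": {0: (15.9949146221, 0.99757), 1: (16.9991315, 0.00038), 2: (17.9991604, 0.00205)},
    "S": {0: (31.97207069, 0.9499), 1: (32.97145850, 0.0075), 2: (33.96786683, 0.0425), 4: (35.96708088, 0.0001)},
}

#: Standard atomic weights (abundance-averaged masses), Da.
AVERAGE_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

#: Monoisotopic masses of the 20 standard amino-acid residues, Da.
RESIDUE_MONO_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average masses of the 20 standard amino-acid residues, Da.
RESIDUE_AVG_MASS = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576, "N": 114.1026,
    "D": 115.0874, "Q": 128.1292, "K": 128.1723, "E": 129.1140, "M": 131.1961,
    "H": 137.1393, "F": 147.1739, "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}

#: Unweighted mean of the 20 residue average masses, Da.  Used to estimate
#: protein length (and hence fragment-report count) from a precursor mass.
MEAN_RESIDUE_AVG_MASS = sum(RESIDUE_AVG_MASS.values()) / len(RESIDUE_AVG_MASS)
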
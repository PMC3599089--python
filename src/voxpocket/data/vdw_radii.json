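{
  "_comment": "Van der Waals radii in Angstrom (Bondi 1964, J. Phys. Chem. 68:441, plus common metals from Batsanov 2001). Fallback for unlisted elements: 1.5 A.",
  "H": 1.20,
  "D": 1.20,
  "HE": 1.40,
  "LI": 1.82,
  "BE": 1.53,
  "B": 1.92,
  "C": 1.70,
  "N": 1.55,
  "O": 1.52,
  "F": 1.47,
  "NE": 1.54,
  "NA": 2.27,
  "MG": 1.73,
  "AL": 1.84,
  "SI": 2.10,
  "P": 1.80,
  "S": 1.80,
  "CL": 1.75,
  "AR": 1.88,
  "K": 2.75,
  "CA": 2.31,
  "MN": 2.05,
  "FE": 2.05,
  "CO": 2.00,
  "NI": 1.63,
  "CU": 1.40,
  "ZN": 1.39,
  "GA": 1.87,
  "AS": 1.85,
  "SE": 1.90,
  "BR": 1.85,
  "KR": 2.02,
  "MO": 2.10,
  "CD": 1.58,
  "I": 1.98,
  "XE": 2.16,
  "HG": 1.55,
  "PB": 2.02
}
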
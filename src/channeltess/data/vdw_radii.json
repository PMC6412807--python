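{
  "comment": "Bondi-style van der Waals radii in angstroms; Fe and other metals use common crystallographic conventions where Bondi gives no value.",
  "default": 2.0,
  "radii": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.8,
    "S": 1.8,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.9,
    "B": 1.92,
    "SI": 2.1,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.0,
    "CO": 2.0,
    "NI": 1.63,
    "CU": 1.4,
    "ZN": 1.39,
    "CD": 1.58,
    "HG": 1.55
  }
}
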
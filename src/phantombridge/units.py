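"""Unit conventions and physical constants.

The package fixes one unit chain and converts at the edges:

* emission energies in MeV, yields per decay;
* specific absorbed fractions (SAF, the symbol ``phi``) in g^-1;
* region masses in g;
* time-integrated activity (TIA) in MBq*s (1 MBq*s = 1e6 decays);
* S values in mGy per MBq*s;
* absorbed doses in mGy.

1 MeV = 1.602176634e-13 J, so 1 MeV/g deposited per decay is
1.602176634e-10 Gy per decay.
"""

#: Gy per decay for an energy deposition of 1 MeV per gram.
GY_PER_DECAY_PER_MEV_PER_G: float = 1.602176634e-10

#: Decays per MBq*s of time-integrated activity.
DECAYS_PER_MBQ_S: float = 1.0e6

#: mGy per Gy.
MGY_PER_GY: float = 1.0e3

#: S-value conversion: (MeV * g^-1 per decay) -> mGy per MBq*s.
S_VALUE_MGY_PER_MBQ_S: float = (
    GY_PER_DECAY_PER_MEV_PER_G * DECAYS_PER_MBQ_S * MGY_PER_GY
)

#: Default unit labels used in reports and CSV headers.
TIA_UNITS = "MBq*s"
DOSE_UNITS = "mGy"
S_VALUE_UNITS = "mGy/(MBq*s)"
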
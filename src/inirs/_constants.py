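"""Centralized unit-conversion constants.

Internal computations mix CGS length units (cm) with seconds; public
interfaces accept the field's customary units: picoseconds for time of
flight, nanometres for wavelength, cm^-1 for optical coefficients and
cm^2/s for diffusion coefficients / blood flow indices.
"""

#: Speed of light in vacuum, cm/s.
C_CM_S = 2.99792458e10

#: Picoseconds -> seconds.
PS = 1e-12

#: Nanometres -> centimetres.
NM_CM = 1e-7

#: Micrometres -> centimetres.
UM_CM = 1e-4
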
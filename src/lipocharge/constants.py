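"""Physical constants used throughout the package (SI units)."""

from scipy import constants as _sc

#: Faraday constant, C mol^-1 (value conventionally used in membrane
#: electrochemistry; agrees with CODATA to the digits quoted).
FARADAY = 96485.332

#: Avogadro constant, mol^-1 (exact, SI 2019).
AVOGADRO = 6.02214076e23

#: Elementary charge, C (exact, SI 2019).
ELEMENTARY_CHARGE = _sc.elementary_charge

#: Boltzmann constant, J K^-1 (exact, SI 2019).
BOLTZMANN = _sc.Boltzmann

#: Vacuum permittivity, F m^-1.
VACUUM_PERMITTIVITY = _sc.epsilon_0

#: Ångström in metres.
ANGSTROM = 1e-10
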
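"""Physical constants used across the package.

Lengths are handled in the units conventional for each subfield: geometry in
mm, optical coefficients in 1/cm at the API surface (converted to 1/mm
internally), nanoparticle dimensions in nm.
"""

#: hc in eV·nm, so photon_energy(lambda_nm) = HC_EV_NM / lambda_nm.
HC_EV_NM = 1239.842

#: Elementary charge in coulomb; also the J/eV conversion factor.
E_CHARGE = 1.602176634e-19

#: Speed of light, m/s.
C_LIGHT = 2.99792458e8

#: hbar in eV·s (for converting eV energies to angular frequencies).
HBAR_EV_S = 6.582119569e-16
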
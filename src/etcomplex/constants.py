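"""Physical constants in the unit systems used across the package.

Two unit systems coexist:

* force-spectroscopy: pN, nm, K (``KB_PN_NM``)
* Brownian dynamics:  kJ/mol, Angstrom, ns (``KB_KJ_MOL``)
"""

#: Boltzmann constant, pN nm / K
KB_PN_NM = 1.380649e-2

#: Boltzmann constant, kJ / (mol K)
KB_KJ_MOL = 8.31446261815324e-3

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: Coulomb constant e^2/(4 pi eps0), kJ Angstrom / mol / e^2 (vacuum)
COULOMB_KJ_A = 1389.35457644382

#: relative dielectric of water used for screened electrostatics
WATER_DIELECTRIC = 78.5

#: dynamic viscosity of water at ~298 K, Pa s
WATER_VISCOSITY = 0.89e-3


def kbt_pn_nm(temperature_K: float) -> float:
    """Thermal energy in pN nm."""
    return KB_PN_NM * temperature_K


def kbt_kj_mol(temperature_K: float) -> float:
    """Thermal energy in kJ/mol."""
    return KB_KJ_MOL * temperature_K


def debye_length_A(ionic_strength_mM: float, temperature_K: float = 298.0) -> float:
    """Debye screening length in Angstrom for a 1:1 electrolyte.

    lambda_D = sqrt(eps_r eps_0 kB T / (2 NA e^2 I)); evaluates to
    ~3.04 Angstrom / sqrt(I[M]) at 298 K in water.
    """
    if ionic_strength_mM <= 0:
        return float("inf")
    I_M = ionic_strength_mM / 1000.0
    # 3.043 A at 298 K; scale with sqrt(T/298) for the explicit T dependence
    return 3.043 / (I_M**0.5) * (temperature_K / 298.0) ** 0.5
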
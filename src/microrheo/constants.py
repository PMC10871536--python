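"""Physical constants and the package-wide unit system.

All analysis code works in a single unit system chosen so that stress comes
out in SI pascals without conversion factors:

* length   — micrometres (μm)
* time     — seconds (s)
* force    — piconewtons (pN)
* stress, moduli — Pa  (1 pN/μm² == 1 Pa exactly)
* viscosity — Pa·s
* trap/spring stiffness — pN/μm
* friction — pN·s/μm
* temperature — kelvin (file inputs may carry °C and are converted on read)

Energy in this system is pN·μm = 1e-18 J, hence the ``KB_PNUM`` convenience
constant below.
"""

#: Boltzmann constant, J/K (exact, 2019 SI definition).
K_B = 1.380649e-23

#: Molar gas constant, J/(mol·K) (exact).
R_GAS = 8.314462618

#: Boltzmann constant expressed in pN·μm/K (1 J = 1e18 pN·μm).
KB_PNUM = K_B * 1e18

#: Reference temperature for reporting activation energies in RT units, K
#: (25 °C convention).
T_REF_RT = 298.15


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from degrees Celsius to kelvin."""
    return float(t_celsius) + 273.15


def kelvin_to_celsius(t_kelvin: float) -> float:
    """Convert a temperature from kelvin to degrees Celsius."""
    return float(t_kelvin) - 273.15
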
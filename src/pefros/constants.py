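"""Physical constants and water-property correlations.

All defaults are module-level so scenario configs can override the derived
quantities (density, heat capacity) without touching the constants themselves.
"""

from __future__ import annotations

import math

#: Faraday constant (C mol^-1)
FARADAY = 96485.0

#: Avogadro constant (mol^-1)
AVOGADRO = 6.022e23

#: Density of water near room temperature (kg m^-3)
WATER_DENSITY = 998.0

#: Specific heat capacity of water (J kg^-1 K^-1)
WATER_HEAT_CAPACITY = 4180.0

#: Molar concentration of pure water (mol L^-1)
WATER_MOLARITY = 55.34

# Vogel-Fulcher-Tammann fit to the dynamic viscosity of liquid water,
# eta(T) = A * exp(B / (T - C)) with T in kelvin and eta in mPa s.
# Parameters from the standard fit to the IAPWS/CRC tabulation, valid
# roughly 0-100 degC; we restrict use to 0-60 degC.
_VOGEL_A = 0.02939  # mPa s
_VOGEL_B = 507.88   # K
_VOGEL_C = 149.3    # K

VISCOSITY_T_MIN_C = 0.0
VISCOSITY_T_MAX_C = 60.0


def water_viscosity(temperature_c: float) -> float:
    """Dynamic viscosity of water in mPa s at ``temperature_c`` (degC).

    Vogel-type correlation; raises ``ValueError`` outside 0-60 degC where the
    fit is used here.
    """
    if not (VISCOSITY_T_MIN_C <= temperature_c <= VISCOSITY_T_MAX_C):
        raise ValueError(
            f"temperature {temperature_c} degC outside viscosity correlation "
            f"range [{VISCOSITY_T_MIN_C}, {VISCOSITY_T_MAX_C}] degC"
        )
    t_k = temperature_c + 273.15
    return _VOGEL_A * math.exp(_VOGEL_B / (t_k - _VOGEL_C))
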
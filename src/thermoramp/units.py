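"""Dissolved-oxygen unit conversions for freshwater respirometry.

Optode channels report water O2 as percent air saturation; metabolic-rate
arithmetic needs mass concentration. Conversion goes through the equilibrium
(100% air saturation) concentration of O2 in freshwater at 1 atm total
pressure, computed with the Benson–Krause formulation used by standard
dissolved-oxygen saturation tables. Salinity is fixed at zero: the protocol
runs in freshwater.
"""

from __future__ import annotations

import numpy as np

# Benson–Krause coefficients for ln(C*) with C* in mg O2 L^-1 and T in kelvin,
# freshwater, 101.325 kPa total pressure.
_BK_COEFFS = (-139.34411, 1.575701e5, -6.642308e7, 1.2438e10, -8.621949e11)

#: Validity range of the solubility formulation, °C.
TEMP_RANGE_C = (0.0, 40.0)


def o2_saturation_mgL(temp_c):
    """Equilibrium O2 concentration (mg L^-1) of air-saturated freshwater.

    Parameters
    ----------
    temp_c : float or array-like
        Water temperature in °C, within ``TEMP_RANGE_C``.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < TEMP_RANGE_C[0]) or np.any(t > TEMP_RANGE_C[1]):
        raise ValueError(
            f"temperature outside solubility validity range {TEMP_RANGE_C}: {temp_c!r}"
        )
    tk = t + 273.15
    a0, a1, a2, a3, a4 = _BK_COEFFS
    ln_c = a0 + a1 / tk + a2 / tk**2 + a3 / tk**3 + a4 / tk**4
    out = np.exp(ln_c)
    return out if out.ndim else float(out)


def airsat_to_mgL(airsat_pct, temp_c):
    """Convert % air saturation to mg O2 L^-1 at the given temperature."""
    return np.multiply(airsat_pct, 0.01) * o2_saturation_mgL(temp_c)


def mgL_to_airsat(conc_mgL, temp_c):
    """Inverse of :func:`airsat_to_mgL`."""
    return 100.0 * np.asarray(conc_mgL, dtype=float) / o2_saturation_mgL(temp_c)
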
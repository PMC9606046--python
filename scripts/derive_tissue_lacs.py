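"""Derive the default tissue LAC table from published cross-section data.

Mass-attenuation coefficients (cm^2/g) for water and cortical bone at
standard grid energies are taken from the NIST XCOM-style photon attenuation
tables; values at the Lu-176 gamma lines (88, 202, 307 keV) and 511 keV are
obtained by log-log interpolation. Linear attenuation coefficients follow by
multiplying with an assumed density:

* water-based soft tissue: water at density 1.0 g/mL
* lung (inflated): water spectrum at density 0.30 g/mL
* fat: water energy dependence scaled to a 511 keV LAC of 0.086 cm^-1
  (adipose tissue is Compton-dominated, so its energy ratios track water's)
* bone marrow: water energy dependence scaled to 0.098 cm^-1 at 511 keV
* bone: cortical-bone spectrum at an effective density of 1.6 g/mL
  (mineral bone including some marrow)

Run ``python scripts/derive_tissue_lacs.py`` to print the table embedded in
``petmu.phantom``.
"""

import numpy as np

# mu/rho in cm^2/g at grid energies (keV)
WATER = {80: 0.1837, 100: 0.1707, 150: 0.1505, 200: 0.1370, 300: 0.1186,
         400: 0.1061, 500: 0.09687, 600: 0.08956}
CORTICAL_BONE = {80: 0.2229, 100: 0.1855, 150: 0.1480, 200: 0.1309,
                 300: 0.1113, 400: 0.09908, 500: 0.09022, 600: 0.08332}

TARGET_ENERGIES = (88.0, 202.0, 307.0, 511.0)


def loglog_interp(table, energy):
    grid = sorted(table)
    for lo, hi in zip(grid, grid[1:]):
        if lo <= energy <= hi:
            slope = np.log(table[hi] / table[lo]) / np.log(hi / lo)
            return table[lo] * (energy / lo) ** slope
    raise ValueError(f"{energy} keV outside the table grid")


def lac(table, density, energy):
    return density * loglog_interp(table, energy)


def main():
    water = {e: lac(WATER, 1.0, e) for e in TARGET_ENERGIES}
    bone = {e: lac(CORTICAL_BONE, 1.6, e) for e in TARGET_ENERGIES}
    rows = {
        "air": {e: 0.0 for e in TARGET_ENERGIES},
        "lung": {e: 0.30 * water[e] for e in TARGET_ENERGIES},
        "fat": {e: 0.086 / water[511.0] * water[e] for e in TARGET_ENERGIES},
        "soft_tissue": water,
        "bone_marrow": {e: 0.098 / water[511.0] * water[e]
                        for e in TARGET_ENERGIES},
        "bone": bone,
    }
    print(f"{'tissue':<14}" + "".join(f"{e:>10.0f}" for e in TARGET_ENERGIES))
    for name, row in rows.items():
        print(f"{name:<14}" + "".join(f"{row[e]:>10.4f}"
                                      for e in TARGET_ENERGIES))


if __name__ == "__main__":
    main()
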
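"""Generate the committed photon cross-section fixture tables.

Writes one CSV per material under ``src/exitdose/data/xs/`` with columns
(energy MeV; mass attenuation coefficients cm^2/g for photoelectric,
incoherent, pair production, and their total) on an 80-point log grid
covering 1 keV - 7 MeV.

Model behind the numbers (documented in docs/methods.md):

* incoherent -- exact integrated Klein-Nishina cross-section per electron
  times N_A * Z / A (free-electron approximation, no binding / Doppler);
* photoelectric -- per-atom cross-section anchored to published
  mass-attenuation values for oxygen, iron and lead at 0.1 MeV and to
  oxygen/lead at 1 MeV, interpolated quadratically in ln(sigma) vs ln(Z),
  with E^-3 behaviour below 0.1 MeV, a single power law between the anchors
  and E^-1 above 1 MeV; lead additionally carries K (88 keV) and L (13 keV)
  absorption edges as multiplicative jump factors;
* pair production -- Z^2.2 scaling with a ((E - 2*m_e*c^2)/E)^3 threshold
  shape calibrated to oxygen and lead at 6 MeV; exactly zero below
  1.022 MeV;
* coherent (Rayleigh) scattering is deliberately omitted.

Run from the repository root:  python tools/build_xs_tables.py
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

OUT_DIR = Path(__file__).resolve().parents[1] / "src" / "exitdose" / "data" / "xs"

N_AVOGADRO = 6.02214076e23
M_EC2 = 0.510998950  # MeV
R_E_CM = 2.8179403262e-13

# atomic weights
A_OF = {1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 13: 26.982, 14: 28.085,
        16: 32.06, 26: 55.845, 29: 63.546, 51: 121.76, 64: 157.25, 82: 207.2}

# (name, density is kept in the package registry; composition as (Z, mass fraction))
COMPOSITIONS = {
    "water": [(1, 0.1119), (8, 0.8881)],
    "air": [(7, 0.755), (8, 0.245)],
    "vacuum": [(7, 0.755), (8, 0.245)],  # same mass coefficients as air; density ~0
    "carbon_fiber": [(6, 1.0)],
    "foam": [(6, 0.8563), (1, 0.1437)],  # polyethylene-like closed-cell foam
    "copper": [(29, 1.0)],
    "scintillator": [(64, 0.8308), (8, 0.0845), (16, 0.0847)],  # Gd2O2S
    "silicon_panel": [(14, 1.0)],
    "aluminum": [(13, 1.0)],
    "lead": [(82, 1.0)],
    "steel": [(26, 1.0)],
    "lead_antimony": [(82, 0.97), (51, 0.03)],
}

PB_K_EDGE = 0.0880  # MeV
PB_L_EDGE = 0.0130  # MeV


def klein_nishina_total(energy_mev: float) -> float:
    """Integrated Klein-Nishina cross-section per electron, cm^2."""
    a = energy_mev / M_EC2
    t = 1.0 + 2.0 * a
    term1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - math.log(t) / a)
    term2 = math.log(t) / (2.0 * a)
    term3 = (1.0 + 3.0 * a) / t**2
    return 2.0 * math.pi * R_E_CM**2 * (term1 + term2 - term3)


# ln(sigma/barn) anchors for the photoelectric fit
_X_O, _X_FE, _X_PB = math.log(8.0), math.log(26.0), math.log(82.0)
_ANCH_01 = {_X_O: math.log(0.0817), _X_FE: math.log(19.5), _X_PB: math.log(1841.0)}


def _lagrange_quad(x, xs, ys):
    (x0, x1, x2), (y0, y1, y2) = xs, ys
    return (y0 * (x - x1) * (x - x2) / ((x0 - x1) * (x0 - x2))
            + y1 * (x - x0) * (x - x2) / ((x1 - x0) * (x1 - x2))
            + y2 * (x - x0) * (x - x1) / ((x2 - x0) * (x2 - x1)))


def _sigma_pe_01(z: int) -> float:
    """Per-atom photoelectric cross-section at 0.1 MeV, barns."""
    xs = (_X_O, _X_FE, _X_PB)
    ys = tuple(_ANCH_01[x] for x in xs)
    return math.exp(_lagrange_quad(math.log(z), xs, ys))


def _curvature_01() -> float:
    """Curvature of the 0.1 MeV ln(sigma)-ln(Z) Lagrange quadratic."""
    s_of = (_ANCH_01[_X_FE] - _ANCH_01[_X_O]) / (_X_FE - _X_O)
    s_fp = (_ANCH_01[_X_PB] - _ANCH_01[_X_FE]) / (_X_PB - _X_FE)
    return (s_fp - s_of) / (_X_PB - _X_O)


def _z_interp(z: int, sig_o: float, sig_pb: float) -> float:
    """O/Pb-anchored power law in Z with the 0.1 MeV fit's curvature."""
    y_o, y_pb = math.log(sig_o), math.log(sig_pb)
    slope = (y_pb - y_o) / (_X_PB - _X_O)
    x = math.log(z)
    return math.exp(y_o + slope * (x - _X_O)
                    + _curvature_01() * (x - _X_O) * (x - _X_PB))


def _sigma_pe_05(z: int) -> float:
    """Per-atom photoelectric cross-section at 0.5 MeV, barns."""
    return _z_interp(z, 9.0e-4, 29.1)


def _sigma_pe_1(z: int) -> float:
    """Per-atom photoelectric cross-section at 1.0 MeV, barns."""
    return _z_interp(z, 1.36e-4, 6.09)


def sigma_photoelectric(z: int, energy_mev: float) -> float:
    """Per-atom photoelectric cross-section, barns."""
    s1, sm, s2 = _sigma_pe_01(z), _sigma_pe_05(z), _sigma_pe_1(z)
    if energy_mev <= 0.1:
        sig = s1 * (0.1 / energy_mev) ** 3
    elif energy_mev < 0.5:
        p = (math.log(s1) - math.log(sm)) / math.log(5.0)
        sig = s1 * (energy_mev / 0.1) ** (-p)
    elif energy_mev < 1.0:
        p = (math.log(sm) - math.log(s2)) / math.log(2.0)
        sig = sm * (energy_mev / 0.5) ** (-p)
    else:
        sig = s2 / energy_mev
    if z == 82:  # lead K and L edges as jump factors
        if energy_mev < PB_K_EDGE:
            sig *= 0.21
        if energy_mev < PB_L_EDGE:
            sig *= 0.10
    return sig


def sigma_pair(z: int, energy_mev: float) -> float:
    """Per-atom nuclear-field pair-production cross-section, barns."""
    if energy_mev <= 1.022:
        return 0.0
    c = 0.0472 / (8.0**2.2 * ((6.0 - 1.022) / 6.0) ** 3)
    return c * z**2.2 * ((energy_mev - 1.022) / energy_mev) ** 3


def mass_coefficients(composition, energy_mev):
    """(pe, incoherent, pair) mass attenuation coefficients, cm^2/g."""
    pe = inc = pair = 0.0
    for z, w in composition:
        per_gram = N_AVOGADRO / A_OF[z]
        pe += w * sigma_photoelectric(z, energy_mev) * 1e-24 * per_gram
        inc += w * z * klein_nishina_total(energy_mev) * per_gram
        pair += w * sigma_pair(z, energy_mev) * 1e-24 * per_gram
    return pe, inc, pair


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    grid = np.geomspace(0.001, 7.0, 80)
    for name, comp in COMPOSITIONS.items():
        lines = [
            "# Photon mass attenuation coefficient table for material "
            f"'{name}' (generated by tools/build_xs_tables.py)",
            "# energy_mev,mu_rho_photoelectric,mu_rho_incoherent,"
            "mu_rho_pair,mu_rho_total  [MeV, cm^2/g]",
        ]
        for e in grid:
            pe, inc, pair = mass_coefficients(comp, float(e))
            total = pe + inc + pair
            lines.append(
                f"{e:.12e},{pe:.12e},{inc:.12e},{pair:.12e},{total:.12e}")
        (OUT_DIR / f"{name}.csv").write_text("\n".join(lines) + "\n")
        print(f"wrote {name}.csv")


if __name__ == "__main__":
    main()
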
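"""Materials and photon interaction physics.

Each material carries an element composition, a bulk density and a committed
cross-section fixture table (``data/xs/<name>.csv``, generated by
``tools/build_xs_tables.py``) holding mass attenuation coefficients for
photoelectric absorption, incoherent (Compton) scattering and pair production
on a common 80-point log-energy grid over 1 keV - 7 MeV.  Coherent (Rayleigh)
scattering is omitted throughout.

The samplers mirror the numba kernels used by the transport engine, so the
unit-testable Python surface and the production path share one implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from . import kernels
from .kernels import M_EC2, PAIR_THRESHOLD, compton_energy  # noqa: F401

E_MIN, E_MAX = 0.001, 7.0
DEFAULT_CUTOFF = 0.010  # MeV, photon transport cutoff


@dataclass(frozen=True)
class FluorescenceShell:
    """One atomic shell: edge energy, emission lines and yields (energies MeV)."""

    label: str
    edge: float
    lines: tuple  # ((energy, relative intensity), ...)
    fluorescence_yield: float
    vacancy_fraction: float

    def __post_init__(self):
        for e, _p in self.lines:
            if e >= self.edge:
                raise ValueError(
                    f"fluorescence line {e} MeV not below {self.label} edge "
                    f"{self.edge} MeV")


@dataclass(frozen=True)
class Material:
    """A homogeneous material: name, density (g/cm3), composition by mass."""

    name: str
    density: float
    elements: tuple  # ((Z, mass fraction), ...)
    fluorescence: Optional[tuple] = None  # tuple of FluorescenceShell

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(w for _z, w in self.elements)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name} sum to {total}, not 1")


# Lead fluorescence model: K lines (K-alpha/K-beta) and a two-line L group.
PB_FLUORESCENCE = (
    FluorescenceShell("K", 0.0880, ((0.07497, 0.8), (0.08494, 0.2)), 0.96, 0.8),
    FluorescenceShell("L", 0.0130, ((0.01055, 0.55), (0.01261, 0.45)), 0.39, 0.2),
)

_REGISTRY = {
    "water": Material("water", 1.0, ((1, 0.1119), (8, 0.8881))),
    "air": Material("air", 1.204e-3, ((7, 0.755), (8, 0.245))),
    "vacuum": Material("vacuum", 1e-12, ((7, 0.755), (8, 0.245))),
    "carbon_fiber": Material("carbon_fiber", 1.7, ((6, 1.0),)),
    "foam": Material("foam", 0.05, ((6, 0.8563), (1, 0.1437))),
    "copper": Material("copper", 8.9, ((29, 1.0),)),
    "scintillator": Material(
        "scintillator", 7.34, ((64, 0.8308), (8, 0.0845), (16, 0.0847))),
    "silicon_panel": Material("silicon_panel", 2.4, ((14, 1.0),)),
    "aluminum": Material("aluminum", 2.7, ((13, 1.0),)),
    "lead": Material("lead", 11.0, ((82, 1.0),), PB_FLUORESCENCE),
    "steel": Material("steel", 7.87, ((26, 1.0),)),
    "lead_antimony": Material(
        "lead_antimony", 11.0, ((82, 0.97), (51, 0.03)), PB_FLUORESCENCE),
}

MATERIAL_NAMES = tuple(_REGISTRY)


def get_material(name: str) -> Material:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; "
                       f"known: {', '.join(MATERIAL_NAMES)}") from None


class CrossSectionTable:
    """Energy-interpolable mass attenuation coefficients for one material.

    Columns are cm^2/g on a log-spaced grid; interpolation of the total is
    log-log, matching the transport kernels exactly.
    """

    def __init__(self, material: Material):
        self.material = material
        with resources.files("exitdose.data.xs").joinpath(
                f"{material.name}.csv").open("rb") as fh:
            data = np.loadtxt(fh, delimiter=",", comments="#")
        self.energy = data[:, 0]
        self.photoelectric = data[:, 1]
        self.incoherent = data[:, 2]
        self.pair = data[:, 3]
        self.total = data[:, 4]
        if not (np.diff(np.log(self.energy)).std() < 1e-9):
            raise ValueError(f"{material.name}: energy grid is not log-spaced")
        self._loge0 = math.log(self.energy[0])
        self._dloge = math.log(self.energy[1]) - self._loge0
        self._lntot = np.log(self.total)

    def mu_rho_total(self, energy: float) -> float:
        """Log-log interpolated total mass coefficient, cm^2/g."""
        self._check_range(energy)
        f = (math.log(energy) - self._loge0) / self._dloge
        i = min(max(int(f), 0), len(self.energy) - 2)
        f -= i
        return math.exp(self._lntot[i] * (1 - f) + self._lntot[i + 1] * f)

    def _check_range(self, energy: float) -> None:
        if not (E_MIN <= energy <= E_MAX):
            raise ValueError(
                f"energy {energy} MeV outside the tabulated range "
                f"[{E_MIN}, {E_MAX}] MeV for material "
                f"{self.material.name!r}")


_TABLE_CACHE: dict = {}


def get_table(name: str) -> CrossSectionTable:
    if name not in _TABLE_CACHE:
        _TABLE_CACHE[name] = CrossSectionTable(get_material(name))
    return _TABLE_CACHE[name]


def mu_total(material, energy: float) -> float:
    """Total linear attenuation coefficient, 1/cm (density x mu/rho)."""
    mat = material if isinstance(material, Material) else get_material(material)
    return mat.density * get_table(mat.name).mu_rho_total(energy)


def compton_scattered_energy(energy: float, theta: float) -> float:
    """Compton kinematics: scattered photon energy for scattering angle theta."""
    if energy <= 0:
        raise ValueError("energy must be positive")
    if not (0.0 <= theta <= math.pi):
        raise ValueError("theta must lie in [0, pi]")
    return compton_energy(energy, math.cos(theta))


@dataclass(frozen=True)
class InteractionOutcome:
    """Bookkeeping for one interaction vertex (kerma approximation)."""

    kind: str  # photoelectric | compton | pair
    secondary_photons: tuple  # ((energy MeV, direction unit 3-vector), ...)
    deposited: float  # MeV deposited locally

    @property
    def total_energy(self) -> float:
        return self.deposited + sum(e for e, _d in self.secondary_photons)


# ---------------------------------------------------------------------------
# samplers (thin wrappers over the numba kernels)
# ---------------------------------------------------------------------------

def _stream_from(rng: np.random.Generator):
    return kernels.new_stream(int(rng.integers(0, 2**63)))


def sample_compton(energy: float, rng: np.random.Generator):
    """Sample one Klein-Nishina scatter.

    Returns (scattered energy, scattering angle rad, electron energy).
    """
    eprime, costheta = kernels.sample_compton_kernel(energy,
                                                     _stream_from(rng))
    return eprime, math.acos(costheta), energy - eprime


_KIND_NAMES = ("photoelectric", "compton", "pair")
_PACK_SINGLETON = None


def default_pack():
    """Shared MaterialPack over the full registry (lazy singleton)."""
    global _PACK_SINGLETON
    if _PACK_SINGLETON is None:
        _PACK_SINGLETON = MaterialPack()
    return _PACK_SINGLETON


def sample_interaction_kind(material, energy: float,
                            rng: np.random.Generator) -> str:
    """Sample the interaction kind proportionally to partial coefficients."""
    mat = material if isinstance(material, Material) else get_material(material)
    pack = default_pack()
    k = kernels.sample_kind_kernel(pack.index[mat.name], energy, pack.loge0,
                                   pack.dloge, pack.ne, pack.mu4,
                                   _stream_from(rng))
    return _KIND_NAMES[k]


def _isotropic(rng):
    w = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return np.array([s * math.cos(phi), s * math.sin(phi), w])


def sample_photoelectric(material: Material, energy: float,
                         rng: np.random.Generator) -> InteractionOutcome:
    """Photoelectric absorption with optional characteristic fluorescence."""
    secondaries = ()
    deposited = energy
    shells = material.fluorescence or ()
    emitted = False
    for shell in shells:
        if energy <= shell.edge or emitted:
            continue
        if rng.random() < shell.vacancy_fraction or shell is shells[-1]:
            if rng.random() < shell.fluorescence_yield:
                r = rng.random()
                acc = 0.0
                for line_e, p in shell.lines:
                    acc += p
                    if r < acc:
                        secondaries = ((line_e, _isotropic(rng)),)
                        deposited = energy - line_e
                        break
            emitted = True
    return InteractionOutcome("photoelectric", secondaries, deposited)


def sample_pair(energy: float, rng: np.random.Generator) -> InteractionOutcome:
    """Pair production with local positron annihilation."""
    if energy <= PAIR_THRESHOLD:
        raise ValueError(
            f"pair production requires E > {PAIR_THRESHOLD:.4f} MeV, "
            f"got {energy}")
    d = _isotropic(rng)
    secondaries = ((kernels.ANNIH_E, d), (kernels.ANNIH_E, -d))
    return InteractionOutcome("pair", secondaries, energy - PAIR_THRESHOLD)


# ---------------------------------------------------------------------------
# kernel packs
# ---------------------------------------------------------------------------

class MaterialPack:
    """All materials flattened into kernel-ready arrays (linear coefficients)."""

    def __init__(self, names: Sequence[str] = MATERIAL_NAMES,
                 cutoff: float = DEFAULT_CUTOFF):
        self.names = tuple(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.cutoff = cutoff
        tables = [get_table(n) for n in self.names]
        e0 = tables[0].energy
        for t in tables[1:]:
            if not np.allclose(t.energy, e0):
                raise ValueError("cross-section tables use different grids")
        ne = len(e0)
        nm = len(self.names)
        self.loge0 = math.log(e0[0])
        self.dloge = math.log(e0[1]) - self.loge0
        self.ne = ne
        mu4 = np.zeros((nm, ne, 4))
        for i, t in enumerate(tables):
            rho = get_material(self.names[i]).density
            mu4[i, :, 0] = t.photoelectric * rho
            mu4[i, :, 1] = t.incoherent * rho
            mu4[i, :, 2] = t.pair * rho
            mu4[i, :, 3] = t.total * rho
        self.mu4 = mu4
        self.lnmu = np.log(np.maximum(mu4[:, :, 3], 1e-300))
        # fluorescence arrays
        self.fl_has = np.zeros(nm, dtype=np.uint8)
        self.fl_kedge = np.zeros(nm)
        self.fl_ledge = np.zeros(nm)
        self.fl_kvac = np.zeros(nm)
        self.fl_kyield = np.zeros(nm)
        self.fl_klines = np.zeros((nm, 2))
        self.fl_kprobs = np.zeros((nm, 2))
        self.fl_lyield = np.zeros(nm)
        self.fl_llines = np.zeros((nm, 2))
        self.fl_lprobs = np.zeros((nm, 2))
        for i, n in enumerate(self.names):
            mat = get_material(n)
            if not mat.fluorescence:
                continue
            k, l = mat.fluorescence
            self.fl_has[i] = 1
            self.fl_kedge[i] = k.edge
            self.fl_kvac[i] = k.vacancy_fraction
            self.fl_kyield[i] = k.fluorescence_yield
            self.fl_klines[i] = [e for e, _p in k.lines]
            self.fl_kprobs[i] = [p for _e, p in k.lines]
            self.fl_ledge[i] = l.edge
            self.fl_lyield[i] = l.fluorescence_yield
            self.fl_llines[i] = [e for e, _p in l.lines]
            self.fl_lprobs[i] = [p for _e, p in l.lines]

    def mu_args(self):
        return (self.loge0, self.dloge, self.ne, self.mu4, self.lnmu,
                self.cutoff)

    def fluor_args(self):
        return (self.fl_has, self.fl_kedge, self.fl_ledge, self.fl_kvac,
                self.fl_kyield, self.fl_klines, self.fl_kprobs,
                self.fl_lyield, self.fl_llines, self.fl_lprobs)
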